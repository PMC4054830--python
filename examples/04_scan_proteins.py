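"""Scan query proteins for predicted methylation sites.

Trains a model on synthetic data, writes a query FASTA, and runs the
whole-protein scan that the command-line `methylsite predict` wraps.
"""

import tempfile
from pathlib import Path

from methylsite import train_svm
from methylsite.app import format_prediction_text, predict_fasta
from methylsite.curation import write_fasta
from methylsite.physchem import PropensityDisorderProvider
from methylsite.profiles import SubstitutionMatrixProvider
from methylsite.synthetic import SyntheticConfig, balanced_feature_set, generate_records

X, y = balanced_feature_set(
    SyntheticConfig(n_proteins=100, seed=3), n_per_class=40, partition_seed=3
)
model = train_svm(X, y, c=8.0, gamma=2.0 ** -6)

queries = generate_records(SyntheticConfig(n_proteins=2, seed=99))
with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "query.fasta"
    write_fasta({r.accession: r.sequence for r in queries}, fasta)
    report = predict_fasta(
        fasta, "R", model,
        SubstitutionMatrixProvider(), PropensityDisorderProvider(),
    )

print(format_prediction_text(report))
print("Every Arg in each query is windowed, encoded and classified; a")
print("positive label means the decision value was at or above the zero")
print("threshold. Per-site decision values are available for ranking.")
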