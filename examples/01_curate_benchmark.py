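"""Curate a peptide benchmark from annotated proteins.

Generates a small synthetic set of annotated proteins, builds the
positive/negative 11-mer benchmark for Arg sites, and partitions the
negatives into near-balanced subsets.
"""

from methylsite import build_benchmark, count_peptide_space, partition_negatives
from methylsite.synthetic import SyntheticConfig, generate_records

records = generate_records(SyntheticConfig(n_proteins=40, seed=1))
dataset = build_benchmark(records, residue_type="R", xi=5)
partition = partition_negatives(dataset, n_subsets=7, seed=0)

print(f"proteins: {len(records)}")
print(f"positive 11-mers: {len(dataset.positives)}")
print(f"negative 11-mers: {len(dataset.negatives)}")
print(f"negative subset sizes: {partition.sizes}")
print(f"distinct 11-mers with a fixed centre: {count_peptide_space(5):.4e}")
print()
print("Positives are windows whose central Arg is annotated as methylated;")
print("negatives are all remaining Arg windows. Subset sizes differ by at")
print("most one so each subset + positives is a near-balanced dataset. The")
print("last number shows why exhaustive experimental annotation of the")
print("window space (20^10 peptides) is infeasible.")
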