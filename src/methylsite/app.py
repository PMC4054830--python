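"""Whole-protein site scanning: the prediction front end.

Given query proteins in FASTA and a trained model, every R (or K) residue is
windowed, encoded with the configured profile and disorder providers, and
classified.  The report lists, per protein, the total number of candidate
sites and each site's 1-based position, predicted label and decision value.
Sequences containing non-standard residues are skipped with a warning rather
than aborting the batch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .curation import (
    DEFAULT_XI,
    PeptideSample,
    _AA_SET,
    enumerate_sites,
    extract_window,
    read_fasta,
)
from .encoder import encode_dataset
from .model import TrainedModel
from .model import predict_labels as _predict_labels

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Unusable query input (empty FASTA, missing file, ...)."""


@dataclass
class SitePrediction:
    position: int  # 1-based
    label: int  # +1 methylated, -1 not
    decision_value: float


@dataclass
class ProteinPrediction:
    accession: str
    n_sites: int
    sites: list[SitePrediction]


@dataclass
class PredictionReport:
    mode: str  # "R" or "K"
    proteins: list[ProteinPrediction]


def predict_fasta(
    fasta_path: str | Path,
    mode: str,
    model: TrainedModel,
    profile_provider,
    disorder_provider,
    xi: int = DEFAULT_XI,
) -> PredictionReport:
    """Scan every R (or K) site of every query protein and classify it."""
    sequences = read_fasta(fasta_path)
    if not sequences:
        raise InputError(f"no sequences found in {fasta_path}")
    proteins = []
    for acc, seq in sequences.items():
        bad = set(seq) - _AA_SET
        if bad:
            logger.warning(
                "%s skipped: non-standard residues %s", acc, sorted(bad)
            )
            continue
        positions = enumerate_sites(seq, mode)
        samples = [
            PeptideSample(
                peptide=extract_window(seq, p, xi),
                center_type=mode,
                label=-1,  # placeholder; labels are being predicted
                source_accession=acc,
                center_pos=p,
            )
            for p in positions
        ]
        sites: list[SitePrediction] = []
        if samples:
            X, _ = encode_dataset(
                samples, {acc: seq}, profile_provider, disorder_provider, xi
            )
            labels, decisions = _predict_labels(model, X)
            sites = [
                SitePrediction(position=p, label=int(l), decision_value=float(d))
                for p, l, d in zip(positions, labels, decisions)
            ]
        proteins.append(
            ProteinPrediction(accession=acc, n_sites=len(positions), sites=sites)
        )
    return PredictionReport(mode=mode, proteins=proteins)


def write_prediction_tsv(report: PredictionReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["accession", "position", "residue_type", "label", "decision_value"]
        )
        for prot in report.proteins:
            for s in prot.sites:
                writer.writerow(
                    [
                        prot.accession,
                        s.position,
                        report.mode,
                        f"{s.label:+d}",
                        f"{s.decision_value:.6f}",
                    ]
                )


def format_prediction_text(report: PredictionReport) -> str:
    """Human-readable summary, one paragraph per protein."""
    name = "Arg (R)" if report.mode == "R" else "Lys (K)"
    lines = []
    for prot in report.proteins:
        methylated = [s.position for s in prot.sites if s.label == 1]
        lines.append(
            f"The total number of {name} in protein {prot.accession} is "
            f"{prot.n_sites}."
        )
        if methylated:
            pos_list = ", ".join(str(p) for p in methylated)
            lines.append(
                f"  Predicted methylation sites: sequence position(s) {pos_list}; "
                f"the remaining {prot.n_sites - len(methylated)} site(s) are "
                f"predicted non-methylated."
            )
        else:
            lines.append("  No site is predicted to be methylated.")
    return "\n".join(lines) + "\n"
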