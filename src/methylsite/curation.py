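"""Benchmark curation for methylation-site prediction.

Builds positive/negative peptide benchmarks from annotated protein records.
Every arginine (R) or lysine (K) in a protein defines a candidate site; the
site is represented by the 2*xi+1 residue window centred on it (11-mer for
the default xi=5).  Windows overhanging a terminus are completed by repeating
the terminal residue.  Windows annotated as experimentally methylated are
positives, all remaining windows of the same centre type are negatives.
Duplicate windows are reduced to one representative per label set, and any
window occurring with both labels (a self-conflict) is dropped from both.

Because negatives outnumber positives roughly seven to one, the negative set
is randomly partitioned into near-equal subsets so that each subset together
with the positives forms an approximately balanced dataset.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 native amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue types that can carry protein methylation.
METHYL_RESIDUES = ("R", "K")

#: Label conventions for classifier input.
POSITIVE_LABEL = 1
NEGATIVE_LABEL = -1

#: Default window half-width; the window length is 2*xi + 1 = 11.
DEFAULT_XI = 5

#: Documented fixed default seed for the negative-subset partition, so that
#: published runs are reproducible without extra bookkeeping.
DEFAULT_PARTITION_SEED = 0

#: Default number of negative subsets (class imbalance is roughly 1:7).
DEFAULT_N_SUBSETS = 7


class CurationError(ValueError):
    """Invalid input to a curation operation."""


class InvalidResidueError(CurationError):
    """A character outside the 20 native amino-acid codes was encountered."""


@dataclass
class ProteinRecord:
    """A protein sequence with experimental methylation annotations.

    ``methyl_sites`` maps residue type ("R" or "K") to a set of 1-based
    sequence positions annotated as methylated.
    """

    accession: str
    sequence: str
    methyl_sites: dict[str, set[int]] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.sequence:
            raise CurationError(f"{self.accession}: empty sequence")
        for residue_type, positions in self.methyl_sites.items():
            if residue_type not in METHYL_RESIDUES:
                raise CurationError(
                    f"{self.accession}: unsupported residue type {residue_type!r}"
                )
            for pos in positions:
                if not 1 <= pos <= len(self.sequence):
                    raise CurationError(
                        f"{self.accession}: annotated position {pos} outside "
                        f"sequence of length {len(self.sequence)}"
                    )
                if self.sequence[pos - 1] != residue_type:
                    raise CurationError(
                        f"{self.accession}: position {pos} is "
                        f"{self.sequence[pos - 1]!r}, annotated as {residue_type!r}"
                    )


@dataclass(frozen=True)
class PeptideSample:
    """A centred candidate-site window with its label and provenance."""

    peptide: str
    center_type: str
    label: int  # +1 methylated, -1 not
    source_accession: str
    center_pos: int  # 1-based position of the centre residue in the protein


@dataclass
class BenchmarkDataset:
    """Curated positive and negative peptide sets for one residue type."""

    residue_type: str
    positives: list[PeptideSample]
    negatives: list[PeptideSample]
    xi: int = DEFAULT_XI


@dataclass
class NegativeSubsetPartition:
    """A seeded random partition of the negative set into near-equal subsets."""

    subsets: list[list[PeptideSample]]
    seed: int

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]


def extract_window(sequence: str, center_pos: int, xi: int = DEFAULT_XI) -> str:
    """Return the 2*xi+1 window of ``sequence`` centred at ``center_pos``.

    Positions before residue 1 are filled with residue 1's character, and
    positions past the C-terminus with the last residue's character (the
    nearest existing neighbour in either direction).

    Parameters
    ----------
    sequence : str
        Protein sequence over the 20 native codes.
    center_pos : int
        1-based centre position.
    xi : int
        Window half-width (non-negative).
    """
    if xi < 0:
        raise CurationError(f"xi must be non-negative, got {xi}")
    if not 1 <= center_pos <= len(sequence):
        raise CurationError(
            f"center position {center_pos} outside sequence of length {len(sequence)}"
        )
    last = len(sequence) - 1
    chars = []
    for offset in range(-xi, xi + 1):
        idx = min(max(center_pos - 1 + offset, 0), last)
        c = sequence[idx]
        if c not in _AA_SET:
            raise InvalidResidueError(
                f"non-standard residue {c!r} at position {idx + 1} in window "
                f"around {center_pos}"
            )
        chars.append(c)
    return "".join(chars)


def enumerate_sites(sequence: str, residue_type: str) -> list[int]:
    """All 1-based positions of ``residue_type`` in ``sequence``, increasing."""
    if residue_type not in METHYL_RESIDUES:
        raise CurationError(f"residue_type must be one of {METHYL_RESIDUES}")
    return [i + 1 for i, c in enumerate(sequence) if c == residue_type]


def count_peptide_space(xi: int) -> int:
    """Number of distinct 2*xi+1 windows with a fixed centre: 20**(2*xi).

    Exact arbitrary-precision integer (1.0240e13 for xi=5).
    """
    if xi < 0:
        raise CurationError(f"xi must be non-negative, got {xi}")
    return 20 ** (2 * xi)


def _dedup_first(samples: Iterable[PeptideSample]) -> list[PeptideSample]:
    seen: set[str] = set()
    out = []
    for s in samples:
        if s.peptide not in seen:
            seen.add(s.peptide)
            out.append(s)
    return out


def build_benchmark(
    records: Sequence[ProteinRecord], residue_type: str, xi: int = DEFAULT_XI
) -> BenchmarkDataset:
    """Curate a benchmark dataset for one residue type.

    Every R (or K) in every record yields a window; windows at annotated
    positions are positive, the rest negative.  Within each label set
    duplicate peptide strings are reduced to the first occurrence (input
    order); peptides occurring with both labels are removed from both sets.
    Windows touching a non-standard residue are skipped with a warning.
    """
    if residue_type not in METHYL_RESIDUES:
        raise CurationError(f"residue_type must be one of {METHYL_RESIDUES}")
    positives: list[PeptideSample] = []
    negatives: list[PeptideSample] = []
    for rec in records:
        rec.validate()
        annotated = rec.methyl_sites.get(residue_type, set())
        for pos in enumerate_sites(rec.sequence, residue_type):
            try:
                peptide = extract_window(rec.sequence, pos, xi)
            except InvalidResidueError as exc:
                logger.warning("%s position %d skipped: %s", rec.accession, pos, exc)
                continue
            sample = PeptideSample(
                peptide=peptide,
                center_type=residue_type,
                label=POSITIVE_LABEL if pos in annotated else NEGATIVE_LABEL,
                source_accession=rec.accession,
                center_pos=pos,
            )
            (positives if sample.label == POSITIVE_LABEL else negatives).append(sample)
    positives = _dedup_first(positives)
    negatives = _dedup_first(negatives)
    conflicts = {s.peptide for s in positives} & {s.peptide for s in negatives}
    if conflicts:
        logger.info("removing %d self-conflicting peptides", len(conflicts))
    positives = [s for s in positives if s.peptide not in conflicts]
    negatives = [s for s in negatives if s.peptide not in conflicts]
    return BenchmarkDataset(residue_type, positives, negatives, xi)


def partition_negatives(
    negatives: BenchmarkDataset | Sequence,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = DEFAULT_PARTITION_SEED,
) -> NegativeSubsetPartition:
    """Randomly split the negative set into ``n_subsets`` near-equal parts.

    A seeded random permutation is applied first; subset sizes differ by at
    most one.  Deterministic for a fixed seed.
    """
    if isinstance(negatives, BenchmarkDataset):
        items = list(negatives.negatives)
    else:
        items = list(negatives)
    if not 1 <= n_subsets <= len(items):
        raise CurationError(
            f"n_subsets must be in [1, {len(items)}], got {n_subsets}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    bounds = np.array_split(np.arange(len(items)), n_subsets)
    subsets = [[shuffled[i] for i in chunk] for chunk in bounds]
    return NegativeSubsetPartition(subsets=subsets, seed=seed)


# ---------------------------------------------------------------------------
# I/O: FASTA sequences, annotation TSV, benchmark TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {accession: sequence}.

    The accession is the header token up to the first whitespace.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path) -> dict[str, dict[str, set[int]]]:
    """Read a site-annotation TSV (accession, residue_type, position)."""
    sites: dict[str, dict[str, set[int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        required = {"accession", "residue_type", "position"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CurationError(
                f"annotation file must have columns {sorted(required)}"
            )
        for row in reader:
            acc = row["accession"]
            rt = row["residue_type"]
            pos = int(row["position"])
            sites.setdefault(acc, {}).setdefault(rt, set()).add(pos)
    return sites


def write_annotations(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["accession", "residue_type", "position"])
        for rec in records:
            for rt in sorted(rec.methyl_sites):
                for pos in sorted(rec.methyl_sites[rt]):
                    writer.writerow([rec.accession, rt, pos])


def load_records(
    fasta_path: str | Path, annotations_path: str | Path
) -> list[ProteinRecord]:
    """Join a FASTA file and an annotation TSV into ProteinRecords."""
    seqs = read_fasta(fasta_path)
    sites = read_annotations(annotations_path)
    unknown = set(sites) - set(seqs)
    if unknown:
        raise CurationError(
            f"annotations refer to accessions absent from FASTA: {sorted(unknown)}"
        )
    return [
        ProteinRecord(acc, seq, {k: set(v) for k, v in sites.get(acc, {}).items()})
        for acc, seq in seqs.items()
    ]


def write_benchmark(dataset: BenchmarkDataset, path: str | Path) -> None:
    """Write a benchmark TSV: peptide, label (+1/-1), accession, center_pos, residue_type."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["peptide", "label", "accession", "center_pos", "residue_type"])
        for s in list(dataset.positives) + list(dataset.negatives):
            writer.writerow(
                [s.peptide, f"{s.label:+d}", s.source_accession, s.center_pos, s.center_type]
            )


def read_benchmark(path: str | Path) -> BenchmarkDataset:
    positives: list[PeptideSample] = []
    negatives: list[PeptideSample] = []
    residue_type = None
    xi = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sample = PeptideSample(
                peptide=row["peptide"],
                center_type=row["residue_type"],
                label=int(row["label"]),
                source_accession=row["accession"],
                center_pos=int(row["center_pos"]),
            )
            residue_type = sample.center_type
            xi = (len(sample.peptide) - 1) // 2
            (positives if sample.label == POSITIVE_LABEL else negatives).append(sample)
    if residue_type is None:
        raise CurationError(f"benchmark file {path} contains no samples")
    return BenchmarkDataset(residue_type, positives, negatives, xi or DEFAULT_XI)
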