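"""Evolutionary profiles (PSSM) for peptide windows.

A window of length 11 is described by an 11x20 matrix of evolution scores:
entry (i, j) scores the substitution of window position i by amino-acid type
j, with types ordered alphabetically by one-letter code.  Raw scores come
either from an external iterative profile search (PSI-BLAST ASCII PSSM files,
three iterations, E-value cutoff 0.001 against a large sequence database) or
from an offline substitution-matrix fallback (BLOSUM62 rows per residue).
Raw scores are squashed elementwise into (0, 1) with the standard sigmoid.

Providers operate on the full protein and slice window rows from it, using
the same terminal-repeat fill rule as window extraction; the fallback
provider is equivalent to scoring the filled 11-mer directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit

from .curation import AMINO_ACIDS, DEFAULT_XI, InvalidResidueError, extract_window

#: Column order used by the profile-search tool's ASCII PSSM output.
BLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Index map: alphabetical output column -> position in the tool's order.
BLAST_TO_ALPHABETICAL = np.array(
    [BLAST_COLUMN_ORDER.index(aa) for aa in AMINO_ACIDS]
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ProfileError(ValueError):
    """Invalid profile data."""


class PssmParseError(ProfileError):
    """Malformed ASCII PSSM table."""


class PssmConsistencyError(PssmParseError):
    """Parsed PSSM row count disagrees with the protein length."""


@dataclass
class RawProfile:
    """Window-by-type matrix of raw evolution scores (rows x 20)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ProfileError(
                f"profile must be 2-D with 20 columns, got shape {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ProfileError("profile contains non-finite entries")


@dataclass
class NormalizedProfile:
    """Sigmoid-squashed profile; every entry strictly inside (0, 1)."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ProfileError(
                f"profile must be 2-D with 20 columns, got shape {self.scores.shape}"
            )
        if not np.all((self.scores > 0.0) & (self.scores < 1.0)):
            raise ProfileError("normalized profile entries must lie in (0, 1)")


def sigmoid_normalize(raw: RawProfile) -> NormalizedProfile:
    """Map every raw score m0 to 1 / (1 + exp(-m0)), preserving shape.

    Scores large enough to saturate in double precision are nudged to the
    nearest representable value inside (0, 1) so the open-interval contract
    holds for any finite input.
    """
    lo = np.nextafter(0.0, 1.0)
    hi = np.nextafter(1.0, 0.0)
    return NormalizedProfile(np.clip(expit(raw.scores), lo, hi))


def remap_blast_columns(matrix: np.ndarray) -> np.ndarray:
    """Reorder 20 columns from the search tool's native order to alphabetical."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 20:
        raise ProfileError(f"expected an Nx20 matrix, got shape {matrix.shape}")
    return matrix[:, BLAST_TO_ALPHABETICAL]


def parse_ascii_pssm(
    text: str, expected_length: int | None = None
) -> tuple[str, np.ndarray]:
    """Parse the standard ASCII PSSM table of the profile-search tool.

    Returns ``(residues, matrix)`` where ``matrix`` is L x 20 with columns
    remapped to alphabetical order.  Raises :class:`PssmParseError` with the
    offending line number for malformed or truncated tables, and
    :class:`PssmConsistencyError` when the row count disagrees with
    ``expected_length``.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if (
            len(parts) >= 22
            and parts[0].isdigit()
            and len(parts[1]) == 1
            and parts[1].isalpha()
        ):
            try:
                scores = [float(x) for x in parts[2:22]]
            except ValueError as exc:
                raise PssmParseError(f"line {lineno}: unparsable score ({exc})")
            if int(parts[0]) != len(rows) + 1:
                raise PssmParseError(
                    f"line {lineno}: residue index {parts[0]} breaks row order "
                    f"(expected {len(rows) + 1}); table truncated or corrupted"
                )
            rows.append(scores)
            residues.append(parts[1])
    if not rows:
        raise PssmParseError("no PSSM rows found in input")
    if expected_length is not None and len(rows) != expected_length:
        raise PssmConsistencyError(
            f"parsed {len(rows)} PSSM rows but protein has {expected_length} residues"
        )
    return "".join(residues), remap_blast_columns(np.array(rows))


_BLOSUM_CACHE: dict[str, np.ndarray] = {}


def _substitution_rows(name: str = "BLOSUM62") -> np.ndarray:
    """20x20 substitution matrix in alphabetical order (rows and columns)."""
    if name not in _BLOSUM_CACHE:
        mat = substitution_matrices.load(name)
        arr = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                arr[i, j] = mat[a, b]
        _BLOSUM_CACHE[name] = arr
    return _BLOSUM_CACHE[name]


def fallback_profile(window: str, matrix: str = "BLOSUM62") -> RawProfile:
    """Substitution-matrix profile: row i is the matrix row of residue i.

    Deterministic; requires only the window itself, so the whole pipeline can
    run with no external search.
    """
    rows = _substitution_rows(matrix)
    try:
        idx = [_AA_INDEX[c] for c in window]
    except KeyError as exc:
        raise InvalidResidueError(f"non-standard residue {exc.args[0]!r} in window")
    return RawProfile(rows[idx, :])


class SubstitutionMatrixProvider:
    """Offline profile provider backed by a substitution matrix."""

    def __init__(self, matrix: str = "BLOSUM62"):
        self.matrix = matrix
        self.id = f"subst-{matrix.lower()}"

    def window_profile(
        self,
        sequence: str,
        center_pos: int,
        xi: int = DEFAULT_XI,
        accession: str | None = None,
    ) -> RawProfile:
        window = extract_window(sequence, center_pos, xi)
        return fallback_profile(window, self.matrix)


class PssmFileProvider:
    """Profile provider reading precomputed ASCII PSSM files.

    Expects one ``<accession><suffix>`` file per protein under ``directory``,
    produced by the external profile search on the full protein.  Window rows
    are sliced with the terminal-repeat fill rule.  Parsed matrices are cached
    in memory.
    """

    def __init__(self, directory: str | Path, suffix: str = ".pssm"):
        self.directory = Path(directory)
        self.suffix = suffix
        self.id = "pssm-files"
        self._cache: dict[str, np.ndarray] = {}

    def full_profile(self, sequence: str, accession: str) -> np.ndarray:
        if accession not in self._cache:
            path = self.directory / f"{accession}{self.suffix}"
            if not path.exists():
                raise ProfileError(f"no PSSM file for {accession} at {path}")
            _, matrix = parse_ascii_pssm(
                path.read_text(), expected_length=len(sequence)
            )
            self._cache[accession] = matrix
        return self._cache[accession]

    def window_profile(
        self,
        sequence: str,
        center_pos: int,
        xi: int = DEFAULT_XI,
        accession: str | None = None,
    ) -> RawProfile:
        if accession is None:
            raise ProfileError("PssmFileProvider requires the protein accession")
        matrix = self.full_profile(sequence, accession)
        last = len(sequence) - 1
        idx = [
            min(max(center_pos - 1 + off, 0), last) for off in range(-xi, xi + 1)
        ]
        return RawProfile(matrix[idx, :])


def write_profile_rows(matrix: np.ndarray, path: str | Path) -> None:
    """Persist full-protein profile rows as tab-separated 20-column text."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.6g", delimiter="\t")


def read_profile_rows(path: str | Path) -> np.ndarray:
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    if matrix.shape[1] != 20:
        raise ProfileError(f"profile cache {path} is not 20 columns wide")
    return matrix
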