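"""Physicochemical (Atchley-factor) and structural-disorder features.

Each window residue contributes five Atchley factor values (polarity,
secondary-structure propensity, molecular volume, codon diversity,
electrostatic charge), giving 5 x 11 = 55 components, ordered position-outer
and factor-inner: the first five components are the factors of residue 1.

Each window residue also contributes one intrinsic-disorder score in [0, 1],
giving 11 components.  Disorder is context dependent, so it is computed (or
read) for the full protein and sliced per window; window positions
overhanging a terminus reuse the terminal residue's score, mirroring the
window fill rule.  Scores come from an external per-residue disorder
predictor or from an offline propensity-scale fallback.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .curation import AMINO_ACIDS, DEFAULT_XI, InvalidResidueError

ATCHLEY_FACTOR_NAMES = (
    "polarity",
    "secondary_structure",
    "molecular_volume",
    "codon_diversity",
    "electrostatic_charge",
)


class PhyschemError(ValueError):
    pass


def _load_atchley() -> dict[str, np.ndarray]:
    path = resources.files("methylsite").joinpath("data/atchley_factors.tsv")
    table: dict[str, np.ndarray] = {}
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            table[row["residue"]] = np.array(
                [float(row[name]) for name in ATCHLEY_FACTOR_NAMES]
            )
    if sorted(table) != sorted(AMINO_ACIDS):
        raise PhyschemError("Atchley constants file does not cover the 20 residues")
    return table


#: residue -> 5 factor values, loaded once from the shipped constants file.
ATCHLEY_TABLE: dict[str, np.ndarray] = _load_atchley()


def atchley_matrix() -> np.ndarray:
    """20x5 factor table, residues in alphabetical order."""
    return np.vstack([ATCHLEY_TABLE[aa] for aa in AMINO_ACIDS])


def aaf_features(peptide: str) -> np.ndarray:
    """55-vector of Atchley factors: component 5*(l-1)+k is factor k of residue l."""
    try:
        rows = [ATCHLEY_TABLE[c] for c in peptide]
    except KeyError as exc:
        raise InvalidResidueError(
            f"non-standard residue {exc.args[0]!r} in peptide"
        )
    return np.concatenate(rows)


@dataclass
class DisorderTrack:
    """Per-residue disorder scores in [0, 1] for a full protein."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise PhyschemError("disorder track must be 1-D")
        if not np.all((self.scores >= 0.0) & (self.scores <= 1.0)):
            raise PhyschemError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


def disorder_features(
    track: DisorderTrack, window_start: int, xi: int = DEFAULT_XI
) -> np.ndarray:
    """Slice the 2*xi+1 window of disorder scores starting at ``window_start``.

    ``window_start`` is 1-based and may run past either terminus (a centred
    window has window_start = center_pos - xi); overhanging positions reuse
    the terminal residue's score.
    """
    n = 2 * xi + 1
    length = len(track)
    if window_start > length or window_start + n - 1 < 1:
        raise PhyschemError(
            f"window [{window_start}, {window_start + n - 1}] lies outside a "
            f"protein of length {length}"
        )
    idx = np.clip(np.arange(window_start, window_start + n) - 1, 0, length - 1)
    return track.scores[idx]


# ---------------------------------------------------------------------------
# Disorder providers
# ---------------------------------------------------------------------------

#: TOP-IDP per-residue disorder propensity scale (Campen et al. 2008).
#: Higher values = more disorder promoting (P most, W least).
TOP_IDP_SCALE: dict[str, float] = {
    "A": 0.060, "C": 0.020, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}

_SCALE_MIN = min(TOP_IDP_SCALE.values())
_SCALE_MAX = max(TOP_IDP_SCALE.values())


class PropensityDisorderProvider:
    """Offline disorder provider: smoothed per-residue propensity scale.

    The raw propensity of each residue is averaged over a centred smoothing
    window (9 residues by default, truncated at the termini) and min-max
    mapped onto [0, 1] using the scale's range.  Deterministic.
    """

    def __init__(self, smoothing_window: int = 9):
        if smoothing_window < 1 or smoothing_window % 2 == 0:
            raise PhyschemError("smoothing_window must be a positive odd integer")
        self.smoothing_window = smoothing_window
        self.id = f"top-idp-w{smoothing_window}"

    def track(self, sequence: str, accession: str | None = None) -> DisorderTrack:
        try:
            raw = np.array([TOP_IDP_SCALE[c] for c in sequence])
        except KeyError as exc:
            raise InvalidResidueError(
                f"non-standard residue {exc.args[0]!r} in sequence"
            )
        half = self.smoothing_window // 2
        csum = np.concatenate([[0.0], np.cumsum(raw)])
        n = raw.size
        lo = np.clip(np.arange(n) - half, 0, n)
        hi = np.clip(np.arange(n) + half + 1, 0, n)
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)
        scaled = (smoothed - _SCALE_MIN) / (_SCALE_MAX - _SCALE_MIN)
        return DisorderTrack(np.clip(scaled, 0.0, 1.0))


class DisorderFileProvider:
    """Disorder provider reading an external predictor's per-residue output.

    Expects one ``<accession><suffix>`` file per protein: two whitespace
    separated columns, 1-based position and score in [0, 1]; lines starting
    with ``#`` are ignored.
    """

    def __init__(self, directory: str | Path, suffix: str = ".diso"):
        self.directory = Path(directory)
        self.suffix = suffix
        self.id = "disorder-files"
        self._cache: dict[str, DisorderTrack] = {}

    def track_for(self, sequence: str, accession: str) -> DisorderTrack:
        if accession not in self._cache:
            path = self.directory / f"{accession}{self.suffix}"
            if not path.exists():
                raise PhyschemError(f"no disorder file for {accession} at {path}")
            scores: dict[int, float] = {}
            for line in path.read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                pos_s, score_s = line.split()[:2]
                scores[int(pos_s)] = float(score_s)
            if sorted(scores) != list(range(1, len(sequence) + 1)):
                raise PhyschemError(
                    f"{path}: scores do not cover positions 1..{len(sequence)}"
                )
            self._cache[accession] = DisorderTrack(
                np.array([scores[p] for p in range(1, len(sequence) + 1)])
            )
        return self._cache[accession]

    def track(self, sequence: str, accession: str | None = None) -> DisorderTrack:
        if accession is None:
            raise PhyschemError("DisorderFileProvider requires the protein accession")
        return self.track_for(sequence, accession)
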