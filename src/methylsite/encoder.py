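"""Assembly of the 346-dimensional pseudo-amino-acid-composition vector.

A peptide window is encoded as the concatenation of four fixed segments
(1-based, half-open index ranges):

    pssm      [1, 221)   220 sigmoid-normalized profile entries, ordered
                         type-outer / position-inner (components 1..11 are
                         column A over window positions 1..11)
    grey      [221, 281)  60 GM(1,1) triples, three per profile column
    aaf       [281, 336)  55 Atchley factors, five per window residue
    disorder  [336, 347)  11 per-residue disorder scores

The total is 220 + 60 + 55 + 11 = 346.  Schema indices are 1-based in all
user-facing output to match the conventional component numbering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import DEFAULT_XI, PeptideSample
from .grey import grey_features
from .physchem import aaf_features, disorder_features
from .profiles import NormalizedProfile, sigmoid_normalize

SCHEMA_VERSION = "pseaac346-1"

N_FEATURES = 346


class EncodingError(ValueError):
    pass


@dataclass
class FeatureSchema:
    """Named, contiguous 1-based half-open segments covering 1..346."""

    segments: dict[str, tuple[int, int]]

    def lengths(self) -> dict[str, int]:
        return {name: hi - lo for name, (lo, hi) in self.segments.items()}

    def slice_for(self, name: str) -> slice:
        """0-based numpy slice for a named segment."""
        lo, hi = self.segments[name]
        return slice(lo - 1, hi - 1)


def schema_segments() -> FeatureSchema:
    """The fixed 346-component segment table."""
    return FeatureSchema(
        segments={
            "pssm": (1, 221),
            "grey": (221, 281),
            "aaf": (281, 336),
            "disorder": (336, 347),
        }
    )


@dataclass
class FeatureVector:
    """An ordered 346-component encoding of one peptide window."""

    values: np.ndarray
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise EncodingError(
                f"feature vector must have exactly {N_FEATURES} components, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise EncodingError("feature vector contains non-finite entries")


def encode_peptide(
    peptide: str, profile: NormalizedProfile, disorder: np.ndarray
) -> FeatureVector:
    """Encode one 11-mer window into the 346-D feature vector.

    ``profile`` is the window's 11x20 normalized evolution profile and
    ``disorder`` the 11 per-residue disorder scores.
    """
    if len(peptide) != 11:
        raise EncodingError(f"peptide must be an 11-mer, got length {len(peptide)}")
    if profile.scores.shape != (11, 20):
        raise EncodingError(
            f"profile must be 11x20, got shape {profile.scores.shape}"
        )
    disorder = np.asarray(disorder, dtype=float)
    if disorder.shape != (11,):
        raise EncodingError(f"disorder must have 11 entries, got {disorder.shape}")
    if not np.all((disorder >= 0.0) & (disorder <= 1.0)):
        raise EncodingError("disorder scores must lie in [0, 1]")
    # type-outer ordering: transpose puts each amino-acid column's 11
    # positions contiguously.
    pssm_part = profile.scores.T.reshape(-1)
    values = np.concatenate(
        [pssm_part, grey_features(profile), aaf_features(peptide), disorder]
    )
    return FeatureVector(values=values)


def encode_dataset(
    samples: Sequence[PeptideSample],
    sequences: dict[str, str],
    profile_provider,
    disorder_provider,
    xi: int = DEFAULT_XI,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode peptide samples into a feature matrix and a +/-1 label vector.

    Profiles and disorder tracks are obtained from the given providers on the
    full source protein and sliced per window; disorder tracks are cached per
    accession.
    """
    tracks: dict[str, object] = {}
    X = np.empty((len(samples), N_FEATURES))
    y = np.empty(len(samples), dtype=int)
    for i, s in enumerate(samples):
        seq = sequences[s.source_accession]
        raw = profile_provider.window_profile(
            seq, s.center_pos, xi, accession=s.source_accession
        )
        if s.source_accession not in tracks:
            tracks[s.source_accession] = disorder_provider.track(
                seq, accession=s.source_accession
            )
        dis = disorder_features(tracks[s.source_accession], s.center_pos - xi, xi)
        X[i] = encode_peptide(s.peptide, sigmoid_normalize(raw), dis).values
        y[i] = s.label
    return X, y


def write_feature_matrix(
    path: str | Path,
    X: np.ndarray,
    y: np.ndarray,
    schema_version: str = SCHEMA_VERSION,
) -> None:
    """Persist a labelled feature matrix as TSV (label first, then f001..f346)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES or X.shape[0] != y.size:
        raise EncodingError("feature matrix and labels have inconsistent shapes")
    with open(path, "w", newline="") as fh:
        fh.write(f"#schema_version={schema_version}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["label"] + [f"f{i:03d}" for i in range(1, N_FEATURES + 1)])
        for label, row in zip(y, X):
            writer.writerow([f"{label:+d}"] + [f"{v:.10g}" for v in row])


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a labelled feature matrix; returns (X, y, schema_version)."""
    schema_version = SCHEMA_VERSION
    rows = []
    labels = []
    with open(path, newline="") as fh:
        header_seen = False
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key == "schema_version":
                    schema_version = value
                continue
            parts = line.rstrip("\n").split("\t")
            if not header_seen:
                header_seen = True
                continue
            if not parts or parts == [""]:
                continue
            labels.append(int(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    X = np.array(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise EncodingError(f"feature file {path} does not have {N_FEATURES} columns")
    return X, np.array(labels, dtype=int), schema_version
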