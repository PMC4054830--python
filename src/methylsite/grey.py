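"""Grey-model GM(1,1) coefficients as per-column profile descriptors.

For each of the 20 columns of a normalized profile, the 11 scores
m(1) .. m(11) are treated as a short grey-system series.  The GM(1,1)
least-squares problem for one column is B x ~ U with

    B row (k-1) = [-m(k),  -sum_{i<k} m(i) - 0.5 m(k),  1]   for k = 2..11
    U entry (k-1) = m(k) - m(k-1)

and the coefficient triple (a1, a2, b) is the least-squares solution.
Twenty columns x three coefficients give 60 features per profile.  Columns
that make B'B singular (e.g. constant columns) use the minimum-norm
least-squares solution, so a constant column yields the zero triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import NormalizedProfile


class GreyError(ValueError):
    pass


@dataclass
class GreyDesign:
    """Design matrix B ((n-1) x 3) and difference vector U for one column."""

    B: np.ndarray
    U: np.ndarray


@dataclass
class GreyTriple:
    """GM(1,1) coefficients for one profile column."""

    a1: float
    a2: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.b])


def grey_design(column) -> GreyDesign:
    """Build the GM(1,1) design (B, U) from one profile column."""
    m = np.asarray(column, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise GreyError(f"column must be a 1-D series of length >= 2, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise GreyError("column contains non-finite entries")
    partial = np.cumsum(m)[:-1]  # sum_{i=1..k-1} m(i) for k = 2..n
    B = np.column_stack([-m[1:], -partial - 0.5 * m[1:], np.ones(m.size - 1)])
    U = np.diff(m)
    return GreyDesign(B=B, U=U)


def grey_solve(design: GreyDesign) -> GreyTriple:
    """Least-squares solution of B x ~ U; minimum-norm when B'B is singular."""
    B = np.asarray(design.B, dtype=float)
    U = np.asarray(design.U, dtype=float)
    if not (np.all(np.isfinite(B)) and np.all(np.isfinite(U))):
        raise GreyError("design contains non-finite entries")
    x, *_ = np.linalg.lstsq(B, U, rcond=None)
    return GreyTriple(a1=float(x[0]), a2=float(x[1]), b=float(x[2]))


def grey_features(profile: NormalizedProfile) -> np.ndarray:
    """Concatenated (a1, a2, b) triples for all 20 columns: a 60-vector.

    Columns are processed in alphabetical amino-acid order, so components
    (3j-2, 3j-1, 3j) belong to column j.
    """
    out = np.empty(60)
    for j in range(20):
        triple = grey_solve(grey_design(profile.scores[:, j]))
        out[3 * j : 3 * j + 3] = triple.as_array()
    return out
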