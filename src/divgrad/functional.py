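"""Distance-based functional Hill numbers (Chiu & Chao framework).

Functional diversity is measured from a symmetric matrix of pairwise trait
distances d_ij and a relative-abundance vector p.  Rao's quadratic entropy

    Q = sum_ij d_ij p_i p_j

is the abundance-weighted mean pairwise distance.  The functional Hill
number of order q treats each unit of pairwise distance as an "entity":

    qD(Q) = [ sum_ij (d_ij / Q) (p_i p_j)^q ] ** (1 / (2 (1 - q)))   (q != 1)
    1D(Q) = exp( -1/2 * sum_ij (d_ij / Q) p_i p_j ln(p_i p_j) )

qD(Q) is the effective number of equally abundant, equally distinct
"virtual" species; total functional diversity is Q * qD(Q)^2 (effective
total distance).  When all off-diagonal distances are equal, qD(Q)
collapses exactly to the taxonomic Hill number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taxonomic import _Q_ONE_WINDOW

__all__ = [
    "FunctionalDistanceMatrix",
    "trait_distance",
    "rao_Q",
    "hill_functional",
]


@dataclass(frozen=True)
class FunctionalDistanceMatrix:
    """Symmetric pairwise trait distances over an ordered taxon list."""

    taxa: tuple
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "d", d)

    def subset(self, taxa: Sequence[str]) -> "FunctionalDistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return FunctionalDistanceMatrix(tuple(taxa), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.taxa), columns=list(self.taxa))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FunctionalDistanceMatrix":
        return cls(tuple(df.index), df.to_numpy(dtype=float))


def trait_distance(
    tt, method: str = "gower", standardization: str | None = None
) -> FunctionalDistanceMatrix:
    """Pairwise functional distances from a trait table.

    Parameters
    ----------
    tt : TraitTable
        Per-taxon SLA, LT, WD values (complete records only).
    method : {"gower", "euclidean"}
        ``gower``: per-trait range normalisation, mean absolute difference
        over traits; distances lie in [0, 1].  This is the default for
        mixed-scale plant traits.  ``euclidean``: Euclidean distance on
        z-scored traits.
    standardization : optional
        Ignored for ``gower`` (range normalisation is intrinsic); for
        ``euclidean`` only "zscore" (default) is available.

    A trait constant across all taxa carries no distance information: under
    Gower it is dropped with a warning; if every trait is constant an error
    is raised.
    """
    import warnings

    df = tt.to_frame()
    if len(df) < 2:
        raise ValueError("need at least 2 taxa to build a distance matrix")
    X = df.to_numpy(dtype=float)
    taxa = tuple(df.index)
    if method == "gower":
        rng = X.max(axis=0) - X.min(axis=0)
        keep = rng > 0
        if not keep.any():
            raise ValueError("all traits are constant; distances undefined")
        if not keep.all():
            dropped = [c for c, k in zip(df.columns, keep) if not k]
            warnings.warn(f"constant traits dropped from Gower distance: {dropped}")
        Xn = X[:, keep] / rng[keep]
        diff = np.abs(Xn[:, None, :] - Xn[None, :, :])
        d = diff.mean(axis=2)
    elif method == "euclidean":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant trait; z-scoring undefined")
        Z = (X - X.mean(axis=0)) / sd
        diff = Z[:, None, :] - Z[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown distance method: {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return FunctionalDistanceMatrix(taxa, d)


def rao_Q(d: FunctionalDistanceMatrix | np.ndarray, p) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    Q = 0 iff all positive-abundance taxa are functionally identical; the
    functional Hill numbers are then undefined and downstream code returns
    1 effective entity by convention.
    """
    dm = d.d if isinstance(d, FunctionalDistanceMatrix) else np.asarray(d, float)
    pv = np.asarray(p, dtype=float)
    pv = pv / pv.sum()
    if dm.shape[0] != pv.size:
        raise ValueError("distance matrix and abundance vector are misaligned")
    return float(pv @ dm @ pv)


def hill_functional(
    d: FunctionalDistanceMatrix | np.ndarray, p, q: float
) -> tuple[float, float]:
    """Functional Hill number of order q.

    Returns
    -------
    (equiv_species_number, total_FD)
        ``equiv_species_number`` is qD(Q), the effective number of equally
        distinct species (the quantity reported as "functional entities");
        ``total_FD`` = Q * qD(Q)^2 is the effective total pairwise distance.
        When Q = 0 (all taxa functionally identical) both default to
        (1.0, 0.0): one functional entity carrying no distance.
    """
    if q < 0:
        raise ValueError(f"diversity order q must be >= 0, got {q}")
    dm = d.d if isinstance(d, FunctionalDistanceMatrix) else np.asarray(d, float)
    pv = np.asarray(p, dtype=float)
    keep = pv > 0
    pv = pv[keep]
    dm = dm[np.ix_(keep, keep)]
    pv = pv / pv.sum()
    Q = float(pv @ dm @ pv)
    if Q <= 0.0:
        return 1.0, 0.0
    pp = np.outer(pv, pv)
    w = dm / Q
    if abs(q - 1.0) < _Q_ONE_WINDOW:
        val = float(np.exp(-0.5 * np.sum(w * pp * np.log(pp))))
    else:
        s = float(np.sum(w * pp ** q))
        val = s ** (1.0 / (2.0 * (1.0 - q)))
    return val, Q * val * val
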