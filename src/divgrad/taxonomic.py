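"""Taxonomic Hill numbers: effective numbers of equally abundant taxa.

The Hill number of order ``q`` for a relative-abundance vector ``p`` is

    qD = (sum_i p_i ** q) ** (1 / (1 - q))        (q != 1)
    1D = exp(-sum_i p_i * ln(p_i))                (limit at q = 1)

``q`` tunes sensitivity to rarity: q = 0 is species richness, q = 1 the
exponential of Shannon entropy, q = 2 the inverse Simpson concentration.
All orders obey the replication principle (pooling N equally weighted,
completely distinct communities multiplies qD by N), which is what makes
Hill numbers "effective numbers" rather than entropies.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["hill_taxonomic", "profile_taxonomic", "validate_abundances"]

#: orders closer to 1 than this use the Shannon limit formula
_Q_ONE_WINDOW = 1e-8


def validate_abundances(p: Iterable[float]) -> np.ndarray:
    """Coerce ``p`` to a strictly positive vector summing to 1 (±1e-12 tolerated,
    then renormalised exactly)."""
    arr = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    arr = arr[arr != 0.0]
    if arr.size == 0:
        raise ValueError("abundance vector is empty")
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        # accept raw counts / unnormalised weights
        arr = arr / total
    else:
        arr = arr / arr.sum()
    return arr


def hill_taxonomic(p: Iterable[float], q: float) -> float:
    """Hill number of order ``q`` for relative abundances ``p``.

    Zeros are dropped; unnormalised count vectors are accepted and
    normalised (Hill numbers are scale-invariant in the counts).
    Computation runs in log space so long rare-species tails with tiny
    p_i do not underflow.

    Parameters
    ----------
    p : array-like
        Relative abundances (or raw counts) of the taxa present.
    q : float
        Diversity order, q >= 0.
    """
    if q < 0:
        raise ValueError(f"diversity order q must be >= 0, got {q}")
    arr = validate_abundances(p)
    if q == 0:
        return float(arr.size)  # richness, exactly
    logp = np.log(arr)
    if abs(q - 1.0) < _Q_ONE_WINDOW:
        return float(np.exp(-np.sum(arr * logp)))
    # log sum_i p_i^q = logsumexp(q * log p_i)
    log_sum = logsumexp(q * logp)
    return float(np.exp(log_sum / (1.0 - q)))


def profile_taxonomic(
    cm, q_list: Sequence[float] = (0.0, 1.0, 2.0)
) -> pd.DataFrame:
    """Taxonomic diversity profile for every plot of a community matrix.

    Parameters
    ----------
    cm : CommunityMatrix
        Validated plot x taxon count matrix.
    q_list : sequence of float
        Diversity orders to evaluate.

    Returns
    -------
    DataFrame with columns ``plot, attribute, q, value`` (attribute = "TD"),
    one row per plot x order; plots are processed independently.
    """
    rows = []
    for plot in cm.plots:
        counts = cm.row(plot)
        for q in q_list:
            rows.append(
                {"plot": plot, "attribute": "TD", "q": q,
                 "value": hill_taxonomic(counts, q)}
            )
    return pd.DataFrame(rows)
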