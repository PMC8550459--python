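"""Attention-weight analytics: dispersion, switched-off filters, and rank
agreement between weights trained at adjacent intensities."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .attention import AttentionWeights

__all__ = ["weight_variance", "count_zeroed", "adjacent_alpha_correlation"]


def _values(w) -> np.ndarray:
    if isinstance(w, AttentionWeights):
        return w.values
    return np.asarray(w, dtype=np.float64)


def weight_variance(weights) -> float:
    """Population variance of the gain vector (higher intensity is expected to
    produce more extreme, higher-variance weights)."""
    v = _values(weights)
    if v.size < 2:
        raise ValueError(f"need at least 2 weights; got {v.size}")
    return float(np.var(v))


def count_zeroed(weights, eps: float = 1e-6) -> int:
    """Number of filters turned off (gain <= eps).

    Projection makes exact zeros well defined; the default eps guards
    serialization round-trips.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    return int(np.sum(_values(weights) <= eps))


def adjacent_alpha_correlation(weights_by_alpha) -> list[float]:
    """Spearman rank correlation between each adjacent pair of weight vectors
    (ordered by intensity). Ties get average ranks; a constant vector makes
    the pair's correlation undefined (NaN)."""
    vecs = [_values(w) for w in weights_by_alpha]
    if len(vecs) < 2:
        raise ValueError("need at least two weight vectors")
    n = vecs[0].size
    if any(v.size != n for v in vecs):
        raise ValueError("weight vectors must all have equal length")
    out: list[float] = []
    for a, b in zip(vecs[:-1], vecs[1:]):
        if np.all(a == a[0]) or np.all(b == b[0]):
            out.append(float("nan"))
            continue
        rho = stats.spearmanr(a, b).statistic
        out.append(float(rho))
    return out
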