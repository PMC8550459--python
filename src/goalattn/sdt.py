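"""Signal-detection scoring of target detection under a max decision rule.

A trial is target-present when the target class is (one of) the ground truth
label(s). The model "responds target" when a target class is its top-k
prediction (k=1 by default). Hit and false-alarm rates are converted to
sensitivity d' = z(H) - z(F) and criterion location c = -(z(H) + z(F))/2,
with the standard 1/(2n) correction for extreme rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "SDTMetrics",
    "SweepResult",
    "SweepStatistics",
    "decide",
    "score_standard",
    "score_blended",
    "rates",
    "dprime",
    "criterion_location",
    "metrics_from_counts",
    "sweep_statistics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_present(self) -> int:
        return self.hits + self.misses

    @property
    def n_absent(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float


@dataclass
class SweepResult:
    """Per-target-class, per-alpha metric matrices (classes x alpha levels)."""

    targets: tuple[int, ...]
    alphas: tuple[float, ...]
    hit_matrix: np.ndarray
    fa_matrix: np.ndarray
    dprime_matrix: np.ndarray
    criterion_matrix: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.targets), len(self.alphas))
        for name in ("hit_matrix", "fa_matrix", "dprime_matrix", "criterion_matrix"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if m.shape != shape:
                raise ValueError(f"{name} has shape {m.shape}; expected {shape}")
            setattr(self, name, m)

    def statistics(self) -> "SweepStatistics":
        return sweep_statistics(self.dprime_matrix)


@dataclass(frozen=True)
class SweepStatistics:
    """One-way ANOVA across intensity levels plus a paired t-test between the
    two highest-mean levels; degenerate-variance cases are flagged (NaN
    statistic) rather than raised."""

    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float
    paired_t: float
    paired_df: int
    paired_p: float
    best_alpha_index: int
    second_alpha_index: int

    @property
    def anova_defined(self) -> bool:
        return np.isfinite(self.anova_F)

    @property
    def paired_defined(self) -> bool:
        return np.isfinite(self.paired_t)


def decide(probs: np.ndarray, k: int = 1) -> set[int]:
    """The k most probable classes; ties broken toward the lowest class index."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError(f"probs must be a vector; got shape {p.shape}")
    if not np.isclose(p.sum(), 1.0, atol=1e-4):
        raise ValueError(f"probabilities sum to {p.sum():.6f}, not 1")
    if not 1 <= k <= p.size:
        raise ValueError(f"k must be in 1..{p.size}; got {k}")
    order = np.lexsort((np.arange(p.size), -p))
    return set(int(i) for i in order[:k])


def _respond_target(prediction, target: set[int]) -> bool:
    if isinstance(prediction, (set, frozenset)):
        return bool(prediction & target)
    return int(prediction) in target


def score_standard(predictions, labels, target) -> ConfusionCounts:
    """Tally hits/misses/FAs/CRs for single-label trials.

    ``predictions`` may be class ids (max rule) or top-k sets.
    """
    target = set(int(c) for c in target)
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError(f"{len(predictions)} predictions vs {len(labels)} labels")
    h = m = fa = cr = 0
    for pred, lbl in zip(predictions, labels):
        present = int(lbl) in target
        responded = _respond_target(pred, target)
        if present:
            h += responded
            m += not responded
        else:
            fa += responded
            cr += not responded
    return ConfusionCounts(h, m, fa, cr)


def score_blended(predictions, label_pairs, target) -> ConfusionCounts:
    """Tally counts for blended trials carrying two ground-truth labels.

    A trial is target-present when the target is either component class; a
    hit is responding target on such a trial, a false alarm is responding
    target when neither component is the target.
    """
    target = set(int(c) for c in target)
    predictions = list(predictions)
    label_pairs = list(label_pairs)
    if len(predictions) != len(label_pairs):
        raise ValueError(f"{len(predictions)} predictions vs {len(label_pairs)} label pairs")
    h = m = fa = cr = 0
    for pred, pair in zip(predictions, label_pairs):
        a, b = int(pair[0]), int(pair[1])
        if a == b:
            raise ValueError(f"blended trial has identical labels ({a}, {b})")
        present = a in target or b in target
        responded = _respond_target(pred, target)
        if present:
            h += responded
            m += not responded
        else:
            fa += responded
            cr += not responded
    return ConfusionCounts(h, m, fa, cr)


def rates(counts: ConfusionCounts) -> tuple[float, float]:
    """(H, F) from counts, replacing extreme rates 0 and 1 by 1/(2n) and
    1 - 1/(2n) so z-scores stay finite."""
    if counts.n_present == 0 or counts.n_absent == 0:
        raise ValueError("need at least one target-present and one target-absent trial")

    def corrected(numer: int, n: int) -> float:
        r = numer / n
        if r == 0.0:
            return 1.0 / (2 * n)
        if r == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    return corrected(counts.hits, counts.n_present), corrected(
        counts.false_alarms, counts.n_absent
    )


def dprime(H: float, F: float) -> float:
    """Sensitivity z(H) - z(F); rates must lie strictly inside (0, 1)."""
    if not (0.0 < H < 1.0 and 0.0 < F < 1.0):
        raise ValueError(f"rates must be in (0, 1); got H={H}, F={F} (apply rates() first)")
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


def criterion_location(H: float, F: float) -> float:
    """Criterion location c = -(z(H) + z(F))/2; lower is more liberal."""
    if not (0.0 < H < 1.0 and 0.0 < F < 1.0):
        raise ValueError(f"rates must be in (0, 1); got H={H}, F={F} (apply rates() first)")
    return float(-(stats.norm.ppf(H) + stats.norm.ppf(F)) / 2.0)


def metrics_from_counts(counts: ConfusionCounts) -> SDTMetrics:
    H, F = rates(counts)
    return SDTMetrics(H, F, dprime(H, F), criterion_location(H, F))


def sweep_statistics(dprime_matrix: np.ndarray) -> SweepStatistics:
    """One-way ANOVA of d' grouped by intensity level (each (class, alpha)
    cell is one observation) and a paired t-test across classes between the
    highest-mean and second-highest-mean levels.

    With C classes and A levels the ANOVA df are (A-1, A*C-A) and the paired
    df is C-1. Degenerate variance yields NaN statistics, flagged via the
    ``*_defined`` properties.
    """
    d = np.asarray(dprime_matrix, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] < 2 or d.shape[1] < 2:
        raise ValueError(f"need a (classes >= 2) x (levels >= 2) matrix; got {d.shape}")
    C, A = d.shape
    cols = [d[:, j] for j in range(A)]
    anova_df = (A - 1, A * C - A)
    if np.allclose(d, d.flat[0]):
        anova_F, anova_p = float("nan"), float("nan")
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            anova_F, anova_p = stats.f_oneway(*cols)
        anova_F, anova_p = float(anova_F), float(anova_p)

    means = d.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    best, second = int(order[0]), int(order[1])
    diff = d[:, best] - d[:, second]
    paired_df = C - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        paired_t, paired_p = float("nan"), float("nan")
    else:
        t, p = stats.ttest_rel(d[:, best], d[:, second])
        paired_t, paired_p = float(t), float(p)
    return SweepStatistics(
        anova_F=anova_F,
        anova_df=anova_df,
        anova_p=anova_p,
        paired_t=paired_t,
        paired_df=paired_df,
        paired_p=paired_p,
        best_alpha_index=best,
        second_alpha_index=second,
    )
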