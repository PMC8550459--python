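"""Intensity-weighted cross-entropy loss.

The attention intensity alpha in [1/N, 1] sets how much the training loss
favours the target class: a target image's cross-entropy is weighted by
alpha, a non-target image's by (1 - alpha)/(N - 1). At alpha = 1/N every
class carries equal weight (no selective attention); at alpha = 1 non-target
images contribute nothing. Because each epoch subsamples non-target classes,
non-target terms are additionally up-weighted by the inverse realized
sampling fraction so the loss stays an unbiased estimate of the full-data
weighted loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityConfig",
    "cross_entropy",
    "per_image_weight",
    "weighted_batch_loss",
    "subsample_correction",
    "DEFAULT_PROB_FLOOR",
]

DEFAULT_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class IntensityConfig:
    """Attention intensity alpha, class count N, and the target class set."""

    alpha: float
    n_classes: int
    target: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = self.n_classes
        if n < 2:
            raise ValueError(f"n_classes must be >= 2; got {n}")
        if not (1.0 / n <= self.alpha <= 1.0):
            raise ValueError(
                f"alpha must lie in [1/N, 1] = [{1.0 / n:.6g}, 1]; got {self.alpha}"
            )
        tgt = frozenset(int(c) for c in self.target)
        if not tgt:
            raise ValueError("target class set must be non-empty")
        if not tgt <= set(range(n)):
            raise ValueError(f"target classes {sorted(tgt)} not all in 0..{n - 1}")
        object.__setattr__(self, "target", tgt)

    @property
    def nontarget_weight(self) -> float:
        return (1.0 - self.alpha) / (self.n_classes - 1)


def cross_entropy(prob_true_class, floor: float = DEFAULT_PROB_FLOOR):
    """-ln p for the true-class probability (natural log).

    Probabilities at or below zero are clamped to ``floor`` with a warning so
    training stays finite; probabilities above 1 are rejected.
    """
    p = np.asarray(prob_true_class, dtype=np.float64)
    if np.any(p > 1.0 + 1e-12):
        raise ValueError(f"probability above 1: max={p.max()}")
    if np.any(p <= 0.0):
        warnings.warn(
            f"true-class probability <= 0 clamped to floor {floor:g}", RuntimeWarning, stacklevel=2
        )
        p = np.clip(p, floor, None)
    out = -np.log(np.minimum(p, 1.0))
    return float(out) if out.ndim == 0 else out


def per_image_weight(label: int, config: IntensityConfig) -> float:
    """alpha for target-class images, (1 - alpha)/(N - 1) otherwise."""
    if int(label) in config.target:
        return float(config.alpha)
    return config.nontarget_weight


def weighted_batch_loss(
    probs_true: np.ndarray,
    labels: np.ndarray,
    config: IntensityConfig,
    sample_correction: np.ndarray | None = None,
) -> float:
    """Sum over the batch of weight_i * correction_i * CE_i.

    ``sample_correction`` holds the subsampling up-weights (>= 1); target
    images must carry correction 1 (they are never subsampled). Reduction is
    by sum, not mean, so alpha keeps its absolute-class-weight meaning.
    """
    probs_true = np.asarray(probs_true, dtype=np.float64)
    labels = np.asarray(labels)
    if probs_true.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {probs_true.shape[0]} probabilities vs {labels.shape[0]} labels"
        )
    if sample_correction is None:
        sample_correction = np.ones_like(probs_true)
    else:
        sample_correction = np.asarray(sample_correction, dtype=np.float64)
        if sample_correction.shape != labels.shape:
            raise ValueError(
                f"length mismatch: {sample_correction.shape[0]} corrections vs "
                f"{labels.shape[0]} labels"
            )
        if np.any(sample_correction < 1.0 - 1e-12):
            raise ValueError("sample corrections must be >= 1")
        is_target = np.isin(labels, list(config.target))
        if np.any(np.abs(sample_correction[is_target] - 1.0) > 1e-12):
            raise ValueError("target images must have sample correction exactly 1")
    w = np.array([per_image_weight(lbl, config) for lbl in labels])
    return float(np.sum(w * sample_correction * cross_entropy(probs_true)))


def subsample_correction(n_class_images: int, n_sampled: int) -> float:
    """Inverse realized sampling fraction n_c / s_c (>= 1)."""
    if n_sampled <= 0:
        raise ValueError("n_sampled must be >= 1")
    if n_sampled > n_class_images:
        raise ValueError(
            f"n_sampled ({n_sampled}) cannot exceed class size ({n_class_images})"
        )
    return n_class_images / n_sampled
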