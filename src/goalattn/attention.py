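"""Filter-wise goal-directed attention: weights, modulation, and the
modulated classifier.

A single non-negative gain per convolutional filter multiplies that filter's
entire activation map (a Hadamard product broadcast over spatial positions).
Gains start at 1.0 (identity) and are trained while the backbone stays
frozen; a gain of exactly 0 switches the filter off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .backbone import ConvNetClassifier

__all__ = [
    "AttentionWeights",
    "apply_attention",
    "project_nonnegative",
    "ModulatedClassifier",
]


@dataclass(frozen=True)
class AttentionWeights:
    """Per-filter non-negative modulation gains.

    Attributes
    ----------
    values : np.ndarray
        Length-F vector of gains, one per filter; entries >= 0, no upper bound.
    alpha : float or None
        The attention intensity the weights were trained at.
    target : tuple of int
        Target class identifiers.
    backbone_id : str
        Identifier of the frozen backbone the weights belong to.
    """

    values: np.ndarray
    alpha: float | None = None
    target: tuple[int, ...] = field(default_factory=tuple)
    backbone_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size == 0:
            raise ValueError(f"attention weights must be a non-empty vector; got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("attention weights must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "target", tuple(self.target))

    @classmethod
    def initialized(
        cls,
        n_filters: int,
        alpha: float | None = None,
        target: tuple[int, ...] = (),
        backbone_id: str = "",
    ) -> "AttentionWeights":
        """Fresh weights: all exactly 1.0 (identity modulation)."""
        return cls(np.ones(n_filters), alpha=alpha, target=target, backbone_id=backbone_id)

    def __len__(self) -> int:
        return self.values.size

    def save(self, path: str | Path) -> None:
        payload = {
            "values": self.values.tolist(),
            "alpha": self.alpha,
            "target": list(self.target),
            "backbone_id": self.backbone_id,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionWeights":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["values"], dtype=np.float64),
            alpha=d["alpha"],
            target=tuple(d["target"]),
            backbone_id=d["backbone_id"],
        )


def apply_attention(activations: np.ndarray, weights: AttentionWeights) -> np.ndarray:
    """Hadamard modulation: out(h, w, f) = act(h, w, f) * gain[f].

    ``activations`` is (H, W, F) or (N, H, W, F); the gain for filter f is
    shared across all spatial positions (and batch entries).
    """
    a = np.asarray(activations, dtype=np.float64)
    if a.ndim not in (3, 4):
        raise ValueError(f"activations must be (H, W, F) or (N, H, W, F); got {a.shape}")
    if a.shape[-1] != len(weights):
        raise ValueError(
            f"filter-count mismatch: activations have {a.shape[-1]} filters, "
            f"attention weights have length {len(weights)}"
        )
    return a * weights.values


def project_nonnegative(values: np.ndarray | AttentionWeights):
    """Clamp entries below zero to exactly zero (idempotent projection).

    Accepts either a raw vector (returns a vector) or AttentionWeights
    (returns AttentionWeights). Used after every optimizer step so
    "filter turned off" (weight exactly 0) is well defined.
    """
    if isinstance(values, AttentionWeights):
        return replace(values, values=np.maximum(values.values, 0.0))
    return np.maximum(np.asarray(values, dtype=np.float64), 0.0)


class ModulatedClassifier:
    """A frozen backbone with a goal-directed attention layer inserted after a
    named convolutional block.

    The backbone's parameters are never updated through this wrapper; only the
    attention gain vector is trainable.
    """

    def __init__(
        self,
        backbone: ConvNetClassifier,
        attention: AttentionWeights | None = None,
        insertion_point: str | None = None,
    ):
        self.backbone = backbone
        self.insertion_point = insertion_point or backbone.insertion_point_
        # Validate the insertion point and derive its filter count.
        b = backbone._block_index(self.insertion_point)
        n_filters = backbone.n_filters[b - 1]
        if attention is None:
            attention = AttentionWeights.initialized(n_filters, backbone_id=backbone.model_id)
        if len(attention) != n_filters:
            raise ValueError(
                f"attention length {len(attention)} does not match insertion point "
                f"{self.insertion_point!r} with {n_filters} filters"
            )
        self.attention = attention

    @property
    def n_classes(self) -> int:
        return self.backbone.n_classes_

    def insertion_activations(self, X: np.ndarray) -> np.ndarray:
        """Pre-attention activations at the insertion point (no modulation).

        The backbone is frozen, so these can be computed once per image and
        reused across attention-training steps.
        """
        return self.backbone.forward_to(X, self.insertion_point)

    def forward_from_insertion(self, pre_activations: np.ndarray, caches: list | None = None) -> np.ndarray:
        """Probabilities from cached pre-attention activations."""
        modulated = apply_attention(pre_activations, self.attention)
        return self.backbone.forward_from(modulated, self.insertion_point, caches=caches)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward_from_insertion(self.insertion_activations(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return self.backbone.classes_[np.argmax(p, axis=1)]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Alias of predict_proba for a single image or a batch."""
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 3
        if single:
            X = X[None]
        p = self.predict_proba(X)
        return p[0] if single else p

    def loss_and_attention_grad(
        self,
        pre_activations: np.ndarray,
        y_idx: np.ndarray,
        sample_weights: np.ndarray,
        prob_floor: float = 1e-12,
    ) -> tuple[float, np.ndarray]:
        """Weighted cross-entropy (sum reduction) and its gradient w.r.t. the
        attention gains, from cached pre-attention activations.

        sample_weights[i] multiplies image i's cross-entropy; the gradient is
        exact for the softmax + weighted-CE composition.
        """
        n = pre_activations.shape[0]
        caches: list = []
        probs = self.forward_from_insertion(pre_activations, caches=caches)
        p_true = np.clip(probs[np.arange(n), y_idx], prob_floor, None)
        loss = float(np.sum(sample_weights * -np.log(p_true)))

        dlogits = probs - np.eye(probs.shape[1])[y_idx]
        dlogits *= sample_weights[:, None]
        dpost = self.backbone.backward_from(dlogits, self.insertion_point, caches)
        # d loss / d gain[f] = sum over batch and space of dpost * pre_activations
        dgain = np.einsum("nhwf,nhwf->f", dpost, pre_activations)
        return loss, dgain
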