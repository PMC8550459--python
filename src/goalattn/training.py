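"""Training regime for attention weights: per-class splits, per-epoch
non-target subsampling with loss up-weighting, Adam with projected
non-negativity, and relative-improvement early stopping.

Each epoch uses every training image of the target class plus a fresh random
fraction (default 10%) of each non-target class; the subsampled images are
up-weighted by the inverse realized sampling fraction so intensity keeps its
meaning. Validation loss (full validation set, weighted cross-entropy, no
subsampling) is checked every other epoch; training stops when the relative
improvement is below 0.1% at two consecutive checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .attention import AttentionWeights, ModulatedClassifier, project_nonnegative
from .backbone import ConvNetClassifier
from .data import LabeledImage, SplitDataset, images_to_arrays
from .losses import IntensityConfig, per_image_weight, weighted_batch_loss

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "split_dataset",
    "make_epoch_sample",
    "should_stop",
    "train_attention",
    "GoalDirectedAttention",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and sampling settings for one attention-training run."""

    learning_rate: float = 0.0003
    batch_size: int = 16
    max_epochs: int = 5000
    nontarget_fraction: float = 0.1
    check_interval: int = 2
    rel_improve_threshold: float = 0.001
    consecutive_checks_to_stop: int = 2
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if not 0 < self.nontarget_fraction <= 1:
            raise ValueError(f"nontarget_fraction must be in (0, 1]; got {self.nontarget_fraction}")
        if not 0 < self.rel_improve_threshold < 1:
            raise ValueError("rel_improve_threshold must be in (0, 1)")
        if self.check_interval <= 0 or self.consecutive_checks_to_stop <= 0:
            raise ValueError("check_interval and consecutive_checks_to_stop must be positive")


@dataclass
class TrainingLog:
    """Per-epoch training losses, per-check validation losses, and the
    sampled image ids of every epoch (for training-regime equivalence checks)."""

    train_losses: list[float] = field(default_factory=list)
    val_checks: list[tuple[int, float]] = field(default_factory=list)
    stopped_reason: str = ""
    epoch_sample_ids: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_losses)

    def to_csv(self, path: str | Path) -> None:
        val_at = dict(self.val_checks)
        lines = ["epoch,train_loss,val_loss,stopped_reason"]
        for e, tl in enumerate(self.train_losses):
            vl = f"{val_at[e]:.10g}" if e in val_at else ""
            reason = self.stopped_reason if e == self.n_epochs - 1 else ""
            lines.append(f"{e},{tl:.10g},{vl},{reason}")
        Path(path).write_text("\n".join(lines) + "\n")


def split_dataset(
    pool: list[LabeledImage],
    train_fraction: float = 0.9,
    seed: int = 0,
    test_fraction: float = 0.0,
) -> SplitDataset:
    """Per-class random split of an image pool.

    An optional test fraction is carved out first; the remainder is split
    train/validation by ``train_fraction`` (rounded half-up per class).
    Deterministic given ``seed``; every class must keep at least one
    validation image.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(
            f"train_fraction must be in (0, 1) so the validation split is non-empty; "
            f"got {train_fraction}"
        )
    if not 0 <= test_fraction < 1:
        raise ValueError(f"test_fraction must be in [0, 1); got {test_fraction}")
    by_class: dict[int, list[LabeledImage]] = {}
    for img in pool:
        by_class.setdefault(img.label, []).append(img)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 901]))
    train: list[LabeledImage] = []
    val: list[LabeledImage] = []
    test: list[LabeledImage] = []
    for c in sorted(by_class):
        imgs = sorted(by_class[c], key=lambda im: im.id)
        if len(imgs) < 3:
            raise ValueError(f"class {c} has only {len(imgs)} images; at least 3 required")
        order = rng.permutation(len(imgs))
        imgs = [imgs[i] for i in order]
        n_test = _round_half_up(test_fraction * len(imgs))
        rest = imgs[n_test:]
        test.extend(imgs[:n_test])
        n_train = _round_half_up(train_fraction * len(rest))
        if n_train >= len(rest):
            n_train = len(rest) - 1
        if n_train < 1:
            raise ValueError(f"class {c}: split leaves no training images")
        train.extend(rest[:n_train])
        val.extend(rest[n_train:])
    return SplitDataset(train=train, validation=val, test=test)


def make_epoch_sample(
    split: SplitDataset,
    config: IntensityConfig,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray]:
    """One epoch's image ids and per-image subsampling corrections.

    Every training image of each target class is included with correction 1.
    Each non-target class c with n_c training images contributes
    s_c = max(1, round(fraction * n_c)) images drawn without replacement,
    each carrying correction n_c / s_c. A fresh draw is made on every call.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1]; got {fraction}")
    idx = split.class_index["train"]
    ids: list[str] = []
    corrections: list[float] = []
    for c in sorted(idx):
        class_ids = sorted(idx[c])
        if c in config.target:
            ids.extend(class_ids)
            corrections.extend([1.0] * len(class_ids))
        else:
            n_c = len(class_ids)
            s_c = max(1, _round_half_up(fraction * n_c))
            chosen = rng.choice(len(class_ids), size=s_c, replace=False)
            ids.extend(class_ids[i] for i in sorted(chosen))
            corrections.extend([n_c / s_c] * s_c)
    return ids, np.asarray(corrections)


def should_stop(
    validation_losses_at_checks: list[float],
    threshold: float = 0.001,
    consecutive: int = 2,
) -> bool:
    """True iff the last ``consecutive`` relative improvements
    (L_prev - L_curr)/L_prev are each below ``threshold``."""
    losses = list(validation_losses_at_checks)
    if len(losses) < consecutive + 1:
        return False
    recent = losses[-(consecutive + 1) :]
    for prev, curr in zip(recent[:-1], recent[1:]):
        rel = (prev - curr) / prev
        if rel >= threshold:
            return False
    return True


def train_attention(
    model: ModulatedClassifier,
    split: SplitDataset,
    intensity: IntensityConfig,
    train_cfg: TrainConfig,
) -> tuple[AttentionWeights, TrainingLog]:
    """Train the attention gains of ``model`` on ``split`` at the given
    intensity; the backbone stays frozen.

    Returns the trained (non-negative) weights and the training log. Fully
    reproducible given the config seed: the epoch-e sampling stream is derived
    from (seed, e).
    """
    if not np.all(model.attention.values == 1.0):
        raise ValueError("model attention must be initialized to all ones before training")

    by_id = split.by_id()
    X_tr, y_tr, ids_tr = images_to_arrays(split.train)
    X_va, y_va, _ = images_to_arrays(split.validation)
    pre_tr = model.insertion_activations(X_tr)
    pre_va = model.insertion_activations(X_va)
    row_of = {img_id: i for i, img_id in enumerate(ids_tr)}
    class_w = np.array([per_image_weight(lbl, intensity) for lbl in y_tr])

    gain = model.attention.values.copy()
    opt = nn.Adam(train_cfg.learning_rate)
    log = TrainingLog()
    val_losses: list[float] = []
    n_classes = model.n_classes

    def set_gain(g: np.ndarray) -> None:
        model.attention = replace(
            model.attention,
            values=g,
            alpha=intensity.alpha,
            target=tuple(sorted(intensity.target)),
        )

    def validation_loss() -> float:
        probs = model.forward_from_insertion(pre_va)
        p_true = probs[np.arange(len(y_va)), y_va]
        return weighted_batch_loss(np.clip(p_true, 1e-12, 1.0), y_va, intensity)

    stopped = "max_epochs"
    for epoch in range(train_cfg.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence([int(train_cfg.seed), epoch]))
        ep_ids, corr = make_epoch_sample(split, intensity, train_cfg.nontarget_fraction, rng)
        log.epoch_sample_ids.append(tuple(ep_ids))
        rows = np.array([row_of[i] for i in ep_ids])
        order = rng.permutation(len(rows))
        rows, corr = rows[order], corr[order]
        ep_loss = 0.0
        for start in range(0, len(rows), train_cfg.batch_size):
            sel = rows[start : start + train_cfg.batch_size]
            sw = class_w[sel] * corr[start : start + train_cfg.batch_size]
            set_gain(gain)
            loss, dgain = model.loss_and_attention_grad(pre_tr[sel], y_tr[sel], sw)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.step({"gain": gain}, {"gain": dgain})
            gain = project_nonnegative(gain)
            ep_loss += loss
        log.train_losses.append(ep_loss)

        if (epoch + 1) % train_cfg.check_interval == 0:
            set_gain(gain)
            vl = validation_loss()
            if not np.isfinite(vl):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            val_losses.append(vl)
            log.val_checks.append((epoch, vl))
            if should_stop(
                val_losses,
                train_cfg.rel_improve_threshold,
                train_cfg.consecutive_checks_to_stop,
            ):
                stopped = "early_stop"
                break

    log.stopped_reason = stopped
    set_gain(gain)
    weights = replace(
        model.attention,
        backbone_id=model.attention.backbone_id or model.backbone.model_id,
    )
    model.attention = weights
    return weights, log


class GoalDirectedAttention(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator: fit trains a filter-wise attention layer
    for one (target class, alpha) pair on top of a frozen backbone.

    ``fit(X, y)`` performs the full regime internally: a per-class 90/10
    train/validation split, per-epoch non-target subsampling with loss
    up-weighting, Adam with non-negativity projection, and early stopping on
    relative validation-loss improvement.
    """

    def __init__(
        self,
        backbone: ConvNetClassifier,
        alpha: float = 0.5,
        target: tuple[int, ...] = (0,),
        insertion_point: str | None = None,
        learning_rate: float = 0.0003,
        batch_size: int = 16,
        max_epochs: int = 5000,
        nontarget_fraction: float = 0.1,
        check_interval: int = 2,
        rel_improve_threshold: float = 0.001,
        consecutive_checks_to_stop: int = 2,
        train_fraction: float = 0.9,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.alpha = alpha
        self.target = target
        self.insertion_point = insertion_point
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.nontarget_fraction = nontarget_fraction
        self.check_interval = check_interval
        self.rel_improve_threshold = rel_improve_threshold
        self.consecutive_checks_to_stop = consecutive_checks_to_stop
        self.train_fraction = train_fraction
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            nontarget_fraction=self.nontarget_fraction,
            check_interval=self.check_interval,
            rel_improve_threshold=self.rel_improve_threshold,
            consecutive_checks_to_stop=self.consecutive_checks_to_stop,
            train_fraction=self.train_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        pool = [
            LabeledImage(X[i], int(y[i]), f"i{i:06d}") for i in range(X.shape[0])
        ]
        split = split_dataset(pool, self.train_fraction, self.random_state)
        return self.fit_split(split)

    def fit_split(self, split: SplitDataset):
        """Fit from an explicit train/validation split."""
        intensity = IntensityConfig(
            self.alpha, self.backbone.n_classes_, frozenset(int(c) for c in self.target)
        )
        self.model_ = ModulatedClassifier(self.backbone, insertion_point=self.insertion_point)
        weights, log = train_attention(self.model_, split, intensity, self._train_config())
        self.attention_ = weights
        self.attention_weights_ = weights.values
        self.log_ = log
        self.classes_ = self.backbone.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=np.float64))
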