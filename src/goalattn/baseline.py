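"""Non-attentional comparison: retrain only the final fully connected layer of
the frozen backbone with the identical intensity-weighted loss and training
regime, then compare signal-detection metrics against the attention model.

The retrained layer is warm-started from the pre-trained final layer by
default (the transfer-learning framing); a cold start is available.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .backbone import ConvNetClassifier
from .data import LabeledImage, SplitDataset, images_to_arrays
from .losses import IntensityConfig, per_image_weight, weighted_batch_loss
from .training import TrainConfig, TrainingLog, make_epoch_sample, should_stop, split_dataset

__all__ = ["retrain_final_layer", "FinalLayerRetrain", "compare_models", "ComparisonResult"]


def _final_features(backbone: ConvNetClassifier, X: np.ndarray) -> np.ndarray:
    """Flattened activations feeding the final fully connected layer."""
    a = backbone.forward_to(X, f"block{backbone.n_blocks}")
    return a.reshape(a.shape[0], -1)


def retrain_final_layer(
    backbone: ConvNetClassifier,
    split: SplitDataset,
    intensity: IntensityConfig,
    train_cfg: TrainConfig,
    warm_start: bool = True,
) -> tuple[dict[str, np.ndarray], TrainingLog]:
    """Train only the final layer's (W, b) under the same sampling, loss and
    early stopping as attention training; all other parameters stay frozen.

    Under the same seed the per-epoch sampled image ids are byte-identical to
    an attention run (same RNG derivation), so the two regimes are matched.
    Returns ({"dense/W", "dense/b"}, log); the backbone object is not mutated.
    """
    X_tr, y_tr, ids_tr = images_to_arrays(split.train)
    X_va, y_va, _ = images_to_arrays(split.validation)
    feat_tr = _final_features(backbone, X_tr)
    feat_va = _final_features(backbone, X_va)
    row_of = {img_id: i for i, img_id in enumerate(ids_tr)}
    class_w = np.array([per_image_weight(lbl, intensity) for lbl in y_tr])

    if warm_start:
        W = backbone.params_["dense/W"].copy()
        b = backbone.params_["dense/b"].copy()
    else:
        rng0 = np.random.default_rng(np.random.SeedSequence([int(train_cfg.seed), 77]))
        W = rng0.normal(0.0, 0.01, size=backbone.params_["dense/W"].shape)
        b = np.zeros_like(backbone.params_["dense/b"])

    opt = nn.Adam(train_cfg.learning_rate)
    log = TrainingLog()
    val_losses: list[float] = []
    n_classes = backbone.n_classes_
    eye = np.eye(n_classes)

    def val_loss() -> float:
        probs = nn.softmax(feat_va @ W + b)
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
            f = feat_tr[sel]
            probs = nn.softmax(f @ W + b)
            p_true = np.clip(probs[np.arange(len(sel)), y_tr[sel]], 1e-12, None)
            loss = float(np.sum(sw * -np.log(p_true)))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            dlogits = (probs - eye[y_tr[sel]]) * sw[:, None]
            grads = {"W": f.T @ dlogits, "b": dlogits.sum(axis=0)}
            opt.step({"W": W, "b": b}, grads)
            ep_loss += loss
        log.train_losses.append(ep_loss)
        if (epoch + 1) % train_cfg.check_interval == 0:
            vl = val_loss()
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
    return {"dense/W": W, "dense/b": b}, log


def classifier_with_final_layer(
    backbone: ConvNetClassifier, final_params: dict[str, np.ndarray]
) -> ConvNetClassifier:
    """A classifier sharing the backbone's frozen features but using the
    retrained final layer."""
    clone = copy.copy(backbone)
    clone.params_ = dict(backbone.params_)
    clone.params_["dense/W"] = final_params["dense/W"]
    clone.params_["dense/b"] = final_params["dense/b"]
    return clone


class FinalLayerRetrain(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator for the retrain-final-layer baseline.

    Fit retrains only the last fully connected layer with the
    intensity-weighted loss and the same sampling/early-stopping regime as
    attention training.
    """

    def __init__(
        self,
        backbone: ConvNetClassifier,
        alpha: float = 0.5,
        target: tuple[int, ...] = (0,),
        warm_start: bool = True,
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
        self.warm_start = warm_start
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
        pool = [LabeledImage(X[i], int(y[i]), f"i{i:06d}") for i in range(X.shape[0])]
        return self.fit_split(split_dataset(pool, self.train_fraction, self.random_state))

    def fit_split(self, split: SplitDataset):
        intensity = IntensityConfig(
            self.alpha, self.backbone.n_classes_, frozenset(int(c) for c in self.target)
        )
        params, log = retrain_final_layer(
            self.backbone, split, intensity, self._train_config(), self.warm_start
        )
        self.final_params_ = params
        self.log_ = log
        self.model_ = classifier_with_final_layer(self.backbone, params)
        self.classes_ = self.backbone.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=np.float64))


@dataclass
class ComparisonResult:
    """Per-class paired differences (attention minus baseline) of d' and
    criterion at matched alphas, with a paired t-test per alpha."""

    targets: tuple[int, ...]
    alphas: tuple[float, ...]
    delta_dprime: np.ndarray
    delta_criterion: np.ndarray
    t_dprime: np.ndarray
    t_criterion: np.ndarray
    paired_df: int

    def summary(self) -> dict:
        return {
            "alphas": list(self.alphas),
            "mean_delta_dprime": self.delta_dprime.mean(axis=0).tolist(),
            "mean_delta_criterion": self.delta_criterion.mean(axis=0).tolist(),
            "t_dprime": [None if not np.isfinite(t) else t for t in self.t_dprime.tolist()],
            "t_criterion": [
                None if not np.isfinite(t) else t for t in self.t_criterion.tolist()
            ],
            "paired_df": self.paired_df,
        }


def compare_models(attention_sweep, baseline_sweep) -> ComparisonResult:
    """Paired per-class comparison of two sweeps at matched target classes and
    intensities. t statistics are NaN (flagged) when fewer than two classes or
    degenerate difference variance make them undefined."""
    if tuple(attention_sweep.targets) != tuple(baseline_sweep.targets):
        raise ValueError(
            f"target-class mismatch: {attention_sweep.targets} vs {baseline_sweep.targets}"
        )
    if tuple(attention_sweep.alphas) != tuple(baseline_sweep.alphas):
        raise ValueError(f"alpha-grid mismatch: {attention_sweep.alphas} vs {baseline_sweep.alphas}")
    dd = attention_sweep.dprime_matrix - baseline_sweep.dprime_matrix
    dc = attention_sweep.criterion_matrix - baseline_sweep.criterion_matrix
    C, A = dd.shape

    def paired_t(diffs: np.ndarray) -> np.ndarray:
        out = np.full(A, np.nan)
        if C < 2:
            return out
        for j in range(A):
            col = diffs[:, j]
            if np.isclose(col.std(ddof=1), 0.0):
                continue
            out[j] = float(col.mean() / (col.std(ddof=1) / np.sqrt(C)))
        return out

    return ComparisonResult(
        targets=tuple(attention_sweep.targets),
        alphas=tuple(attention_sweep.alphas),
        delta_dprime=dd,
        delta_criterion=dc,
        t_dprime=paired_t(dd),
        t_criterion=paired_t(dc),
        paired_df=C - 1,
    )
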