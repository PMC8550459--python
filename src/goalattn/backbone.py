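"""A small trainable convolutional classifier used as the frozen backbone.

The architecture is a miniature of the classic conv-block design: a stack of
(3x3 conv -> ReLU -> 2x2 max-pool) blocks followed by one fully connected
layer and a softmax over N classes. Any block boundary can serve as the
insertion point for a goal-directed attention layer; the default is the
penultimate convolutional block, i.e. a mid-level representation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

__all__ = ["ConvNetClassifier"]


class ConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional N-way classifier trained with Adam on mean cross-entropy.

    Parameters
    ----------
    n_filters : tuple of int
        Filters per convolutional block; each block halves the spatial size.
    learning_rate, batch_size, max_epochs : optimizer settings.
    patience : int
        Epochs without validation-accuracy improvement before stopping
        (best-epoch parameters are restored).
    val_fraction : float
        Per-class fraction held out internally when ``fit`` is not given an
        explicit validation set.
    random_state : int
        Seed for initialization and epoch shuffling.

    Attributes
    ----------
    params_ : dict of str -> np.ndarray
        All trainable parameters.
    classes_ : np.ndarray
        Sorted class labels.
    insertion_point_ : str
        Name of the default attention insertion block (e.g. ``"block2"``).
    insertion_filters_ : int
        Channel count of the insertion point's output — the length an
        attention weight vector must have.
    val_accuracy_ : float
        Best top-1 validation accuracy reached during ``fit``.
    """

    def __init__(
        self,
        n_filters: tuple[int, ...] = (16, 32, 32),
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 80,
        patience: int = 12,
        val_fraction: float = 0.1,
        random_state: int = 0,
        insertion_block: int | None = None,
        target_val_accuracy: float | None = None,
    ):
        self.n_filters = n_filters
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.insertion_block = insertion_block
        self.target_val_accuracy = target_val_accuracy

    # ------------------------------------------------------------------ setup

    @property
    def n_blocks(self) -> int:
        return len(self.n_filters)

    def _default_insertion(self) -> int:
        # Penultimate conv block (1-based index).
        if self.insertion_block is not None:
            return int(self.insertion_block)
        return max(1, self.n_blocks - 1)

    def initialize(self, image_size: int, n_classes: int, n_channels: int = 3) -> "ConvNetClassifier":
        """Deterministically initialize parameters without training.

        He-normal conv kernels; near-zero final layer so an untrained network
        outputs probabilities close to uniform.
        """
        if image_size % (2**self.n_blocks) != 0:
            raise ValueError(
                f"image_size {image_size} must be divisible by {2 ** self.n_blocks} "
                f"({self.n_blocks} pooling stages)"
            )
        rng = np.random.default_rng(self.random_state)
        params: dict[str, np.ndarray] = {}
        cin = n_channels
        for b, cout in enumerate(self.n_filters, start=1):
            fan_in = 9 * cin
            params[f"conv{b}/W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, cin, cout))
            params[f"conv{b}/b"] = np.zeros(cout)
            cin = cout
        spatial = image_size // (2**self.n_blocks)
        d = spatial * spatial * self.n_filters[-1]
        params["dense/W"] = rng.normal(0.0, 0.01, size=(d, n_classes))
        params["dense/b"] = np.zeros(n_classes)

        self.params_ = params
        self.classes_ = np.arange(n_classes)
        self.image_size_ = int(image_size)
        self.n_channels_ = int(n_channels)
        self.n_classes_ = int(n_classes)
        ins = self._default_insertion()
        self.insertion_point_ = f"block{ins}"
        self.insertion_filters_ = int(self.n_filters[ins - 1])
        self.val_accuracy_ = float("nan")
        self.history_ = []
        return self

    # --------------------------------------------------------------- forward

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(f"expected images of shape (n, H, W, C); got {X.shape}")
        n, h, w, c = X.shape
        if (h, w, c) != (self.image_size_, self.image_size_, self.n_channels_):
            raise ValueError(
                f"input shape {(h, w, c)} does not match backbone contract "
                f"{(self.image_size_, self.image_size_, self.n_channels_)}"
            )
        return X

    def _block_index(self, name: str) -> int:
        if not name.startswith("block"):
            raise ValueError(f"unknown insertion point {name!r}")
        b = int(name[5:])
        if not 1 <= b <= self.n_blocks:
            raise ValueError(f"insertion point {name!r} outside block1..block{self.n_blocks}")
        return b

    def forward_to(self, X: np.ndarray, block: str) -> np.ndarray:
        """Activations at the output of the named block (post ReLU and pool)."""
        upto = self._block_index(block)
        a = self._check_X(X)
        for b in range(1, upto + 1):
            a, _ = nn.conv2d_forward(a, self.params_[f"conv{b}/W"], self.params_[f"conv{b}/b"])
            a, _ = nn.relu_forward(a)
            a, _ = nn.maxpool2_forward(a)
        return a

    def forward_from(self, a: np.ndarray, block: str, caches: list | None = None) -> np.ndarray:
        """Class probabilities from activations at the named block's output.

        If ``caches`` is a list it is filled with the per-layer caches needed
        by :meth:`backward_from`.
        """
        start = self._block_index(block) + 1
        for b in range(start, self.n_blocks + 1):
            a, xp = nn.conv2d_forward(a, self.params_[f"conv{b}/W"], self.params_[f"conv{b}/b"])
            a, rmask = nn.relu_forward(a)
            a, pcache = nn.maxpool2_forward(a)
            if caches is not None:
                caches.append(("block", b, xp, rmask, pcache))
        flat = a.reshape(a.shape[0], -1)
        logits, _ = nn.dense_forward(flat, self.params_["dense/W"], self.params_["dense/b"])
        if caches is not None:
            caches.append(("dense", flat, a.shape))
        return nn.softmax(logits)

    def backward_from(self, dlogits: np.ndarray, block: str, caches: list) -> np.ndarray:
        """Gradient w.r.t. the named block's output activations.

        Backbone parameters receive no updates; only the input gradient is
        propagated (the backbone stays frozen).
        """
        kind, flat, ashape = caches[-1]
        assert kind == "dense"
        da, _, _ = nn.dense_backward(dlogits, flat, self.params_["dense/W"], need_dx=True)
        da = da.reshape(ashape)
        for entry in reversed(caches[:-1]):
            _, b, xp, rmask, pcache = entry
            da = nn.maxpool2_backward(da, pcache)
            da = nn.relu_backward(da, rmask)
            da, _, _ = nn.conv2d_backward(da, xp, self.params_[f"conv{b}/W"], need_dx=True)
        return da

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a = self.forward_to(X, "block1") if self.n_blocks >= 1 else self._check_X(X)
        return self.forward_from(a, "block1")

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]

    # ------------------------------------------------------------------ train

    def _full_forward_backward(self, X, y_idx):
        """Mean cross-entropy loss and gradients for all parameters."""
        n = X.shape[0]
        a = X
        caches = []
        for b in range(1, self.n_blocks + 1):
            a, xp = nn.conv2d_forward(a, self.params_[f"conv{b}/W"], self.params_[f"conv{b}/b"])
            a, rmask = nn.relu_forward(a)
            a, pcache = nn.maxpool2_forward(a)
            caches.append((b, xp, rmask, pcache))
        flat = a.reshape(n, -1)
        logits, _ = nn.dense_forward(flat, self.params_["dense/W"], self.params_["dense/b"])
        probs = nn.softmax(logits)
        p_true = np.clip(probs[np.arange(n), y_idx], 1e-12, None)
        loss = float(-np.log(p_true).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {}
        da, grads["dense/W"], grads["dense/b"] = nn.dense_backward(
            dlogits, flat, self.params_["dense/W"]
        )
        da = da.reshape(a.shape)
        for b, xp, rmask, pcache in reversed(caches):
            da = nn.maxpool2_backward(da, pcache)
            da = nn.relu_backward(da, rmask)
            need_dx = b > 1
            da, gW, gb = nn.conv2d_backward(da, xp, self.params_[f"conv{b}/W"], need_dx=need_dx)
            grads[f"conv{b}/W"] = gW
            grads[f"conv{b}/b"] = gb
        return loss, grads

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError(f"expected images of shape (n, H, W, C); got {X.shape}")
        classes = np.unique(y)
        n_classes = int(classes.max()) + 1 if np.issubdtype(classes.dtype, np.integer) else len(classes)
        self.initialize(X.shape[1], n_classes, X.shape[3])

        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 1]))
        if X_val is None:
            # Per-class holdout for early stopping.
            tr_idx, va_idx = [], []
            for c in np.unique(y):
                idx = np.flatnonzero(y == c)
                idx = idx[rng.permutation(len(idx))]
                n_va = max(1, int(np.floor(self.val_fraction * len(idx) + 0.5)))
                va_idx.extend(idx[:n_va])
                tr_idx.extend(idx[n_va:])
            tr_idx = np.array(sorted(tr_idx))
            va_idx = np.array(sorted(va_idx))
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_val, y_val = X[va_idx], y[va_idx]
        else:
            X_tr, y_tr = X, y
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val)

        y_tr_idx = np.searchsorted(self.classes_, y_tr)
        opt = nn.Adam(self.learning_rate)
        best_acc = -1.0
        best_params = None
        since_best = 0
        n = X_tr.shape[0]
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                loss, grads = self._full_forward_backward(X_tr[sel], y_tr_idx[sel])
                opt.step(self.params_, grads)
                ep_loss += loss * len(sel)
            val_acc = float(np.mean(self.predict(X_val) == y_val))
            self.history_.append({"epoch": epoch, "train_loss": ep_loss / n, "val_acc": val_acc})
            if self.target_val_accuracy is not None and val_acc >= self.target_val_accuracy:
                # Competence-band stop: keep this epoch's parameters as-is.
                best_acc = val_acc
                best_params = None
                break
            if val_acc > best_acc + 1e-12:
                best_acc = val_acc
                best_params = {k: v.copy() for k, v in self.params_.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            self.params_ = best_params
        self.val_accuracy_ = best_acc
        return self

    # ------------------------------------------------------------------- I/O

    @property
    def model_id(self) -> str:
        """Short content hash identifying the parameter state."""
        h = hashlib.sha1()
        for k in sorted(self.params_):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params_[k]).tobytes())
        return h.hexdigest()[:12]

    def snapshot(self) -> dict[str, np.ndarray]:
        """Copy of all parameters, for frozen-backbone assertions."""
        return {k: v.copy() for k, v in self.params_.items()}

    def save(self, path: str | Path) -> None:
        """Write <path>.npz (parameters) and a JSON sidecar with the contract."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params_)
        meta = {
            "insertion_point": self.insertion_point_,
            "filter_count": self.insertion_filters_,
            "n_filters": list(self.n_filters),
            "n_classes": self.n_classes_,
            "image_size": self.image_size_,
            "n_channels": self.n_channels_,
            "model_id": self.model_id,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNetClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(n_filters=tuple(meta["n_filters"]))
        est.initialize(meta["image_size"], meta["n_classes"], meta["n_channels"])
        with np.load(path.with_suffix(".npz")) as z:
            est.params_ = {k: z[k] for k in z.files}
        return est
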