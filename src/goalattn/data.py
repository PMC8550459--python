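"""Core data containers: labeled images, blended images, and dataset splits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledImage", "BlendedImage", "SplitDataset", "images_to_arrays"]


@dataclass(frozen=True)
class LabeledImage:
    """A single training or test stimulus.

    Attributes
    ----------
    pixels : np.ndarray
        Float array of shape (height, width, channels) with values in [0, 1].
    label : int
        Integer class identifier.
    id : str
        Stable identifier, unique within a dataset.
    """

    pixels: np.ndarray
    label: int
    id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3:
            raise ValueError(f"pixels must be (H, W, C); got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError(f"image {self.id!r} has non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(f"image {self.id!r} has pixels outside [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BlendedImage:
    """A pixelwise mix of two images from distinct classes.

    Carries both ground-truth labels; by default the mix is 50/50 so each
    component's pixel values are halved before summation.
    """

    pixels: np.ndarray
    label_a: int
    label_b: int
    source_ids: tuple[str, str]

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise ValueError("blended image requires two distinct labels")
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)

    @property
    def labels(self) -> frozenset[int]:
        return frozenset((self.label_a, self.label_b))


@dataclass
class SplitDataset:
    """Disjoint train / validation / test collections of labeled images."""

    train: list[LabeledImage]
    validation: list[LabeledImage]
    test: list[LabeledImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for part in (self.train, self.validation, self.test):
            for img in part:
                if img.id in seen:
                    raise ValueError(f"image id {img.id!r} appears in more than one split")
                seen.add(img.id)

    @property
    def class_index(self) -> dict[str, dict[int, list[str]]]:
        """Map split name -> class id -> list of image ids."""
        out: dict[str, dict[int, list[str]]] = {}
        for name in ("train", "validation", "test"):
            idx: dict[int, list[str]] = {}
            for img in getattr(self, name):
                idx.setdefault(img.label, []).append(img.id)
            out[name] = idx
        return out

    def classes(self) -> list[int]:
        labels = {img.label for img in self.train}
        return sorted(labels)

    def by_id(self) -> dict[str, LabeledImage]:
        out = {}
        for part in (self.train, self.validation, self.test):
            for img in part:
                out[img.id] = img
        return out


def images_to_arrays(images: list[LabeledImage]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack a list of LabeledImage into (X, y, ids) arrays."""
    if not images:
        raise ValueError("empty image list")
    X = np.stack([img.pixels for img in images]).astype(np.float64)
    y = np.array([img.label for img in images], dtype=np.int64)
    ids = [img.id for img in images]
    return X, y, ids
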