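"""Test-set construction: balanced standard sets, alpha-blended images, and a
directory loader for user-supplied challenge sets (e.g. natural adversarial
photographs organized by class)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .data import BlendedImage, LabeledImage, SplitDataset

__all__ = [
    "blend",
    "assemble_standard_testset",
    "assemble_blended_testset",
    "load_challenge_set",
]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def blend(image_a: LabeledImage, image_b: LabeledImage, mix: float = 0.5) -> BlendedImage:
    """Pixelwise mix: mix*A + (1-mix)*B, clipped to [0, 1].

    At the default mix of 0.5 each component's pixel values are halved and
    summed. The two images must share spatial dimensions and carry distinct
    labels.
    """
    if image_a.pixels.shape != image_b.pixels.shape:
        raise ValueError(
            f"dimension mismatch: {image_a.pixels.shape} vs {image_b.pixels.shape}"
        )
    if image_a.label == image_b.label:
        raise ValueError(f"cannot blend two images of the same class ({image_a.label})")
    if not 0.0 <= mix <= 1.0:
        raise ValueError(f"mix must be in [0, 1]; got {mix}")
    px = np.clip(mix * image_a.pixels + (1.0 - mix) * image_b.pixels, 0.0, 1.0)
    return BlendedImage(
        pixels=px,
        label_a=image_a.label,
        label_b=image_b.label,
        source_ids=(image_a.id, image_b.id),
    )


def assemble_standard_testset(
    split: SplitDataset, target, seed: int = 0
) -> list[LabeledImage]:
    """All target-class test images plus an equal-count random sample of
    non-target test images (uniform over non-target images, without
    replacement). Deterministic given ``seed``."""
    target = set(int(c) for c in target)
    targets = sorted(
        (img for img in split.test if img.label in target), key=lambda im: im.id
    )
    others = sorted(
        (img for img in split.test if img.label not in target), key=lambda im: im.id
    )
    if not targets:
        raise ValueError("no target-class images in the test split")
    if len(others) < len(targets):
        raise ValueError(
            f"cannot balance test set: {len(targets)} target images but only "
            f"{len(others)} non-target images available"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 331]))
    chosen = rng.choice(len(others), size=len(targets), replace=False)
    return targets + [others[i] for i in sorted(chosen)]


def assemble_blended_testset(
    split: SplitDataset,
    target,
    n_per_side: int,
    seed: int = 0,
) -> list[BlendedImage]:
    """n_per_side target-present blends (one component from the target class,
    one from a random other class) and n_per_side target-absent blends (two
    distinct non-target classes). 50/50 mix; deterministic given ``seed``."""
    target = set(int(c) for c in target)
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    by_class: dict[int, list[LabeledImage]] = {}
    for img in sorted(split.test, key=lambda im: im.id):
        by_class.setdefault(img.label, []).append(img)
    target_classes = sorted(c for c in by_class if c in target)
    other_classes = sorted(c for c in by_class if c not in target)
    if not target_classes:
        raise ValueError("no target-class images in the test split")
    if len(other_classes) < 2:
        raise ValueError("need at least two non-target classes with test images")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 557]))

    def draw(classes: list[int]) -> LabeledImage:
        c = classes[rng.integers(len(classes))]
        pool = by_class[c]
        return pool[rng.integers(len(pool))]

    out: list[BlendedImage] = []
    for _ in range(n_per_side):
        a = draw(target_classes)
        b = draw([c for c in other_classes])
        out.append(blend(a, b, 0.5))
    for _ in range(n_per_side):
        ca, cb = rng.choice(len(other_classes), size=2, replace=False)
        a = draw([other_classes[ca]])
        b = draw([other_classes[cb]])
        out.append(blend(a, b, 0.5))
    return out


def load_challenge_set(
    directory: str | Path,
    class_map: dict[str, int],
    image_size: int | None = None,
) -> list[LabeledImage]:
    """Load a class-per-subdirectory image tree into LabeledImages.

    Pixels are scaled to [0, 1]; unknown class directories and non-image
    files are skipped with a warning. ``image_size`` resizes (bilinear) to
    the backbone's input contract.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"{directory} is not a directory")
    out: list[LabeledImage] = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        if sub.name not in class_map:
            logger.warning("skipping unmapped class directory %r", sub.name)
            continue
        label = int(class_map[sub.name])
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in _IMAGE_SUFFIXES:
                logger.warning("skipping non-image file %s", f)
                continue
            with Image.open(f) as im:
                im = im.convert("RGB")
                if image_size is not None:
                    im = im.resize((image_size, image_size), Image.BILINEAR)
                px = np.asarray(im, dtype=np.float64) / 255.0
            out.append(LabeledImage(px, label, f"{sub.name}/{f.name}"))
    if not out:
        raise ValueError(f"no labeled images found under {directory}")
    return out
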