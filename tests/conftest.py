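"""Shared fixtures: a tiny synthetic world and a briefly trained backbone.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from goalattn.backbone import ConvNetClassifier
from goalattn.data import images_to_arrays
from goalattn.synthetic import SyntheticSpec, generate_dataset
from goalattn.training import split_dataset

TINY_SEED = 11


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(n_classes=4, images_per_class=12, image_size=16, seed=TINY_SEED)


@pytest.fixture(scope="session")
def tiny_pool(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_split(tiny_pool):
    return split_dataset(tiny_pool, train_fraction=0.9, seed=TINY_SEED, test_fraction=1.0 / 6.0)


@pytest.fixture(scope="session")
def tiny_backbone(tiny_split) -> ConvNetClassifier:
    X_tr, y_tr, _ = images_to_arrays(tiny_split.train)
    X_va, y_va, _ = images_to_arrays(tiny_split.validation)
    est = ConvNetClassifier(random_state=TINY_SEED, max_epochs=30, patience=30)
    est.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    return est


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
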