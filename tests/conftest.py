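"""Shared fixtures.

The expensive trained models are session-scoped and shared between the unit
tests and the acceptance tests so the whole suite fits a single-CPU budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphovae import (
    ModelConfig,
    build_triplet_dataset,
    make_splits,
    synthetic,
    train_model,
)

FIXTURE_SEED = 7
SPLIT_SEED = 1
TARGET_LENGTH = 80


def small_config(**overrides) -> ModelConfig:
    """The scaled-down architecture used for trained fixtures (single CPU)."""
    base = dict(
        n_classes=3,
        encoder_filters=[8, 8, 8, 8, 16],
        decoder_filters=[16, 8, 8, 8, 8],
        epochs=100,
        seed=0,
        batch_size=64,
        learning_rate=3e-3,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def separable_dataset():
    """3 classes x 60 specimens -> 360 projection triplets, fixed seed."""
    params = synthetic.separable_class_params(3)
    manifest, volumes = synthetic.generate_dataset(params, 60, seed=FIXTURE_SEED)
    ds = build_triplet_dataset(manifest, volumes, target_length_px=TARGET_LENGTH)
    return ds


@pytest.fixture(scope="session")
def separable_split(separable_dataset):
    return make_splits(separable_dataset.parent_manifest(), seed=SPLIT_SEED)


@pytest.fixture(scope="session")
def trained_separable(separable_dataset, separable_split):
    """100-epoch training on the separable fixture (shared; ~4-6 min)."""
    model, history = train_model(separable_dataset, small_config(), separable_split)
    return model, history


@pytest.fixture(scope="session")
def quadrant_fixture():
    """Triplets whose class signal sits in one quadrant of the x channel."""
    X, y, quadrant = synthetic.quadrant_informative_triplets(
        n_per_class=30, n_classes=3, seed=11
    )
    return X, y, quadrant


@pytest.fixture(scope="session")
def trained_quadrant(quadrant_fixture):
    from morphovae.datasets import TripletDataset

    X, y, quadrant = quadrant_fixture
    n = len(X)
    parent_ids = np.array([f"q{i:03d}" for i in range(n)], dtype=object)
    ds = TripletDataset(
        X=X,
        y=y,
        label_names=[f"class{c}" for c in range(3)],
        parent_ids=parent_ids,
        sides=["left"] * n,
    )
    plan = make_splits(ds.parent_manifest(), seed=3)
    cfg = small_config(epochs=40, seed=5)
    model, history = train_model(ds, cfg, plan)
    return model, ds, plan, quadrant


@pytest.fixture(scope="session")
def tiny_alpha_dataset():
    """Smaller separable dataset for the alpha-sweep replication."""
    params = synthetic.separable_class_params(3)
    manifest, volumes = synthetic.generate_dataset(params, 15, seed=21)
    return build_triplet_dataset(manifest, volumes, target_length_px=TARGET_LENGTH)
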