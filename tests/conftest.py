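"""Shared fixtures: the procedural dataset and trained fixture networks.

Training runs once per session at the package's default problem size
(8 categories x 200 samples, 32x32); everything downstream shares the
resulting networks.
"""

from __future__ import annotations

import numpy as np
import pytest

from hallucinet.networks import (
    train_fixture_classifier,
    train_fixture_generator,
)
from hallucinet.synthetic_data import FixtureSpec, generate_dataset, holdout_split

FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def fixture_dataset():
    return generate_dataset(FixtureSpec(samples_per_class=200, seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def split(fixture_dataset):
    return holdout_split(fixture_dataset)


@pytest.fixture(scope="session")
def classifier(fixture_dataset):
    return train_fixture_classifier(fixture_dataset, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def generator(fixture_dataset):
    return train_fixture_generator(fixture_dataset, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def scorer(fixture_dataset):
    """Independently trained classifier used as the inception surrogate, so
    realism is never judged by the network the optimiser climbs."""
    return train_fixture_classifier(fixture_dataset, epochs=20, seed=9,
                                    augment=False)


@pytest.fixture(scope="session")
def input_pool():
    """20 held-out style fixture images (distinct from the training spec)."""
    pool = generate_dataset(FixtureSpec(samples_per_class=3, seed=7))
    return pool.images[:20], pool.labels[:20]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
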