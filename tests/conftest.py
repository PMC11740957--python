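"""Shared fixtures: the canonical synthetic dataset and models trained on
it under the fixture-scale training settings."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from batchvae import BatchVAE, default_fixture, log_cpm, tmm_factors
from batchvae.training import FIXTURE_TRAINING


@pytest.fixture(scope="session")
def fixture_counts():
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_norm(fixture_counts):
    return log_cpm(fixture_counts, tmm_factors(fixture_counts))


@functools.lru_cache(maxsize=None)
def _train_cached(seed: int):
    adata = default_fixture(seed=0)
    norm = log_cpm(adata, tmm_factors(adata))
    model = BatchVAE(**FIXTURE_TRAINING, random_state=seed).fit(norm)
    return model, norm


def train_fixture_model(seed: int = 0):
    """Train (once per session) on the canonical fixture with the given
    weight-init/shuffling seed."""
    return _train_cached(seed)


@pytest.fixture(scope="session")
def trained_model(fixture_norm):
    model, _ = train_fixture_model(0)
    return model


def probe_source_accuracy(X, labels, k: int = 5) -> float:
    """5-fold CV accuracy of a fresh kNN probe predicting the source."""
    from sklearn.model_selection import cross_val_score
    from sklearn.neighbors import KNeighborsClassifier

    return float(
        cross_val_score(KNeighborsClassifier(k), np.asarray(X), labels, cv=5).mean()
    )
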