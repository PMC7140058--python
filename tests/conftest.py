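"""Shared fixtures: one gradient scheme, one trained fraction estimator and
one noisy phantom study are built per session and reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from fwrecur.freewater import make_training_set, train_fraction_estimator
from fwrecur.phantom import build_phantom, simulate_study
from fwrecur.schemes import make_scheme


@pytest.fixture(scope="session")
def scheme32():
    """The default acquisition: 32 directions at b = 800, one b = 0."""
    return make_scheme(32, 800.0, 1, seed=7)


@pytest.fixture(scope="session")
def scheme_small():
    """A cheap 12-direction scheme for fast unit tests."""
    return make_scheme(12, 800.0, 1, seed=3)


@pytest.fixture(scope="session")
def trained_estimator(scheme32):
    """Fraction estimator trained on the full 5e4-sample synthetic set."""
    ts = make_training_set(scheme32, 50_000, seed=1)
    return train_fraction_estimator(ts, seed=2)


@pytest.fixture(scope="session")
def phantom_truth():
    return build_phantom(seed=100)


@pytest.fixture(scope="session")
def phantom_study(phantom_truth, scheme32):
    """SNR-30 noisy acquisition of the session phantom."""
    return simulate_study(phantom_truth, scheme32, snr=30.0, seed=200)
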