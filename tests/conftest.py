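"""Shared fixtures: small synthetic datasets and ensembles.

Everything is generated programmatically with fixed seeds; the heavier
high-separation recovery fixtures are session-scoped so that the
parameter-recovery and consensus-clustering checks share one ensemble.
"""

import warnings

import numpy as np
import pytest

from stablefc.dataio import SessionedTimeSeries, standardize
from stablefc.ensemble import run_ensemble
from stablefc.synthetic import HIGH_SEPARATION, simulate


@pytest.fixture(autouse=True)
def _quiet_near_empty_warnings():
    # tiny fixtures routinely trigger the near-empty-state advisory
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def tiny_ts():
    """Two short sessions, 3 channels, no particular structure."""
    rng = np.random.default_rng(0)
    return SessionedTimeSeries(rng.standard_normal((40, 3)), [25, 15])


@pytest.fixture
def small_easy_ts():
    """Well-separated 2-state data, cheap enough for repeated fits."""
    ts, truth = simulate(2, 4, [300, 300], stay_prob=0.9,
                         separation=HIGH_SEPARATION, seed=5)
    return standardize(ts), truth


@pytest.fixture(scope="session")
def recovery_regime():
    """High-separation 4-state regime: K=4, P=10, T=20,000, stay 0.95."""
    ts, truth = simulate(4, 10, [5000] * 4, stay_prob=0.95,
                         separation=HIGH_SEPARATION, seed=11)
    return standardize(ts), truth


@pytest.fixture(scope="session")
def recovery_ensemble(recovery_regime):
    """Twenty seeded fits on the high-separation regime."""
    ts, _ = recovery_regime
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_ensemble(ts, 4, R=20, base_seed=0)
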