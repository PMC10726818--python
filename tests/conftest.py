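"""Shared fixtures: small simulated subjects and paradigm configurations."""

import logging

import numpy as np
import pytest

from gradreveal.synth import (
    GroundTruth,
    ParadigmConfig,
    ProfileKind,
    simulate_subject,
)

# Keep test output readable; individual tests re-enable what they assert on.
logging.getLogger("gradreveal").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_paradigm():
    """Two short runs, a dozen trials: fast but structurally complete."""
    return ParadigmConfig(n_runs=2, n_trials_total=12)


@pytest.fixture
def default_truth():
    return GroundTruth()


@pytest.fixture
def noiseless_truth():
    """Deterministic behaviour and clean signal for exact checks."""
    return GroundTruth(
        drift_rate={"neutral": 0.1, "high": 0.08},
        threshold={"neutral": 1.0, "high": 1.2},
        rt_noise_sd=0.0,
        accuracy_prob=1.0,
        noise_sd=0.0,
        drift_amplitude=0.0,
        global_amplitude=0.0,
    )


@pytest.fixture
def simulated_subject(default_truth, small_paradigm, rng):
    return simulate_subject(
        default_truth,
        small_paradigm,
        {"acc": ProfileKind.ACCUMULATOR, "amy": ProfileKind.STEP},
        rng=rng,
        subject="sub-01",
    )
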