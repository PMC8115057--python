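import numpy as np
import pytest
from hypothesis import settings

from cbtsim import ExperimentConfig, exposure_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def run_exposure(danger, cab, max_len=200, step=10, seed=SEED, **kw):
    cfg = ExperimentConfig(
        danger_prior=danger,
        cab_i=cab,
        exposure_lengths=tuple(range(0, max_len + 1, step)),
        n_probe_reps=50,
        seed=seed,
        **kw,
    )
    return exposure_experiment(cfg)


@pytest.fixture(scope="session")
def exposure_strong_danger_weak_cab():
    """P(safe)=0.1, CAB-i=0.1: the implicit over-writing route."""
    return run_exposure(0.9, 0.1)


@pytest.fixture(scope="session")
def exposure_strong_danger_strong_cab():
    """P(safe)=0.1, CAB-i=0.9: the explicit belief-updating route."""
    return run_exposure(0.9, 0.9)


@pytest.fixture(scope="session")
def exposure_strong_danger_moderate_cab():
    """P(safe)=0.1, CAB-i=0.5: slow change via explicit route + relearning."""
    return run_exposure(0.9, 0.5, max_len=250)


@pytest.fixture(scope="session")
def exposure_uncertain_weak_cab():
    """P(safe)=0.5, CAB-i=0.1: generalizing implicit learning."""
    return run_exposure(0.5, 0.1, max_len=250)
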