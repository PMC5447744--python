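import numpy as np
import pytest

from p300sae.simulate import NoiseModel, SimulationConfig, SubjectProfile


def central_difference_gradient(f, x, h=1e-5):
    """Central finite differences of a scalar function of a flat vector."""
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def gradient_relative_error(analytic, numeric):
    na, nn = np.linalg.norm(analytic), np.linalg.norm(numeric)
    return np.linalg.norm(analytic - numeric) / max(na, nn, 1e-300)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sim_config():
    """Short sessions (5 targets per phase) for fast pipeline tests."""
    return SimulationConfig(targets_per_phase=5)


@pytest.fixture
def default_profile():
    return SubjectProfile(subject_id="S01")


@pytest.fixture
def quiet_config():
    """Low-noise configuration so responses dominate the signal."""
    return SimulationConfig(
        targets_per_phase=5,
        noise=NoiseModel(pink_sd=0.5, alpha_amplitude=0.2, white_sd=0.1),
    )
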