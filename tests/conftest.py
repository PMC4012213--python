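import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_symmetric_M(rng):
    """Fixed random symmetric 5x5 coupling matrix with zero diagonal."""
    A = rng.normal(size=(5, 5))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


@pytest.fixture
def tiny_config():
    """Desk-scale experiment configuration (N=16, T=50) for pipeline tests."""
    from rewardnet import ExperimentConfig

    return ExperimentConfig.from_mapping(
        {
            "seed": 5,
            "network": {"n_neurons": 16},
            "stimulus": {"T": 50, "onset": 5, "pulse_width": 5, "offset": 30},
            "analysis": {"n_shuffles": 120, "snapshot_every": None},
        }
    )
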