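import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vermispop import pipeline
from vermispop.synthetic_data import (
    Condition,
    Direction,
    GroundTruthNeuron,
    Modality,
    make_active_like_trajectory,
)


@pytest.fixture(scope="session")
def active_stim():
    """Standard whole-body active-like stimulus: 5 ipsi + 5 contra pulses."""
    return make_active_like_trajectory(
        amplitude=30.0, duration_half_cycle=0.5, n_repeats=5
    )


@pytest.fixture(scope="session")
def dynamic_stimuli():
    """All three dynamic conditions on a common grid."""
    return pipeline.standard_stimuli(n_repeats=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def velocity_neuron(
    c_v_ipsi=0.5, c_v_contra=0.5, baseline=120.0, noise_sd=0.0
) -> GroundTruthNeuron:
    """Pure-velocity vestibular cell (true c_p = c_a = 0)."""
    return GroundTruthNeuron(
        id="vel",
        baseline=baseline,
        coeffs={
            (Modality.VESTIBULAR, Direction.IPSI): (0.0, c_v_ipsi, 0.0),
            (Modality.VESTIBULAR, Direction.CONTRA): (0.0, c_v_contra, 0.0),
        },
        noise_sd=noise_sd,
    )
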