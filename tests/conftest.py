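import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from anometry import PullThroughRecording, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(
    pressures: np.ndarray,
    patient_id: str = "P1",
    maneuver_id: int = 1,
    sampling_rate: float = 10.0,
) -> PullThroughRecording:
    """Recording with a valid strictly-decreasing axial axis for given pressures."""
    pressures = np.asarray(pressures, dtype=float)
    n = pressures.shape[0]
    step = 1.0 / sampling_rate
    return PullThroughRecording(
        patient_id=patient_id,
        maneuver_id=maneuver_id,
        axial_positions=3.0 - step * np.arange(n),
        pressures=pressures,
        sampling_rate=sampling_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_free_config():
    """Deterministic recordings: no sensor noise, no artifacts."""
    return SimulationConfig(noise_sd=0.0, artifact_probability=0.0, seed=7)


@pytest.fixture
def fast_config():
    """Tiny recordings (7 samples each) for tests that only need labels/shapes."""
    return SimulationConfig(
        sampling_rate=1.0,
        recording_span=6.0,
        noise_sd=2.0,
        seed=11,
    )
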