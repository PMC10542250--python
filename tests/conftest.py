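import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ergfda as ef

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_waveform(times, amplitudes, wid="w1", group="control", pid="p1", eye="right"):
    return ef.Waveform(
        waveform_id=wid,
        participant_id=pid,
        group=group,
        eye=eye,
        times=np.asarray(times, dtype=float),
        amplitudes=np.asarray(amplitudes, dtype=float),
    )


@pytest.fixture
def triangle_segment():
    """The worked AL-b example: samples (10,-5),(20,3),(30,15)."""
    w = make_waveform([10.0, 20.0, 30.0], [-5.0, 3.0, 15.0])
    pair = ef.LandmarkPair(
        ef.Landmark(10.0, -5.0, "a_min"), ef.Landmark(30.0, 15.0, "b_max")
    )
    return ef.extract_alb_segment(w, pair)


@pytest.fixture
def small_cohort():
    """Deterministic 6-participant-per-group simulated cohort."""
    return ef.simulate_cohort(ef.SimulationConfig(n_per_group=6, seed=11))


def refined_peak_time(grid, y):
    """Peak time with parabolic sub-grid refinement around the argmax.

    The sampling step cannot resolve sub-step peak delays by argmax alone;
    the standard three-point parabola interpolates the vertex.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y, dtype=float)
    j = int(np.argmax(y))
    if j == 0 or j == y.size - 1:
        return float(grid[j])
    denom = y[j - 1] - 2 * y[j] + y[j + 1]
    if denom == 0:
        return float(grid[j])
    delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
    return float(grid[j] + delta * (grid[j + 1] - grid[j]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
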