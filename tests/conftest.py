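import numpy as np
import pytest
from hypothesis import settings

from zebraphys import AcquisitionConfig, ChamberTrace, Trajectory
from zebraphys.config import alternating_schedule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def cardiac_config():
    """200 fps, 10 s — the cardiac/flow recording setup."""
    return AcquisitionConfig(frame_rate=200.0, um_per_pixel=1.0, recording_duration=10.0)


@pytest.fixture
def photomotor_config():
    """Scaled-down photomotor protocol: four alternating 60-s phases, 25 fps."""
    return AcquisitionConfig(
        frame_rate=25.0,
        mm_per_pixel=0.25,
        phase_schedule=alternating_schedule(4, 60.0),
        recording_duration=240.0,
    )


@pytest.fixture
def full_photomotor_config():
    """The full 80-min protocol: eight alternating 10-min phases."""
    return AcquisitionConfig(
        frame_rate=25.0,
        mm_per_pixel=0.25,
        phase_schedule=alternating_schedule(8, 600.0),
        recording_duration=4800.0,
    )


def sinusoid_trace(
    freq_hz=2.5, fps=200.0, duration_s=10.0, mean_long=100.0, mean_short=45.0,
    amp=5.0, noise_sd=0.0, seed=0, subject_id="sin", chamber="ventricle",
):
    """Chamber trace whose short axis is a pure sinusoid (minima = beats)."""
    frames = np.arange(int(round(duration_s * fps)))
    t = frames / fps
    short = mean_short + amp * np.sin(2 * np.pi * freq_hz * t)
    long = mean_long + amp * np.sin(2 * np.pi * freq_hz * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        short = short + rng.normal(0, noise_sd, len(t))
        long = long + rng.normal(0, noise_sd, len(t))
    return ChamberTrace(subject_id, chamber, frames, long, short)


def polygon_loop_trajectory(diameter=4.0, m=36, loops=2, direction="ccw", subject_id="poly"):
    """Closed polygon circuits: m-gon of the given diameter, traversed
    ``loops`` times with two extra vertices so every turn is realized."""
    sgn = 1.0 if direction == "ccw" else -1.0
    ang = sgn * 2 * np.pi / m * np.arange(loops * m + 2)
    r = diameter / 2.0
    x, y = r * np.cos(ang), r * np.sin(ang)
    return Trajectory(subject_id, np.arange(len(x)), x, y)
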