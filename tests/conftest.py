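import warnings

import numpy as np
import pytest
from hypothesis import settings

from egflow.geometry import BasketGeometry, GridLocation
from egflow.synth import WaveScenario, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_short_recording_warnings():
    # most fixtures use short recordings; the <60 s advisory is expected
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="recording is .*")
        warnings.filterwarnings("ignore", message="recording yields .*")
        yield


@pytest.fixture(scope="session")
def geometry():
    return BasketGeometry()


@pytest.fixture(scope="session")
def clean_focal_recording():
    """Noise-free repetitive focal source at E5 (4,4): 4 s, no QRST."""
    scn = WaveScenario(
        kind="planar_sr",
        origin=GridLocation(4, 4),
        cycle_length_ms=100.0,
        noise_sd=0.0,
        qrst_amplitude_mv=0.0,
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec, truth = simulate(scn, duration=4.0)
    return rec, truth


def radial_source_field(shape=(32, 29), center=(16, 14), magnitude=1.0):
    """Ideal centrifugal (divergent) flow field around a pixel."""
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy, dx = r - center[0], c - center[1]
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    return magnitude * dx / norm, magnitude * dy / norm


def vortex_field(shape=(32, 29), center=(16, 14), magnitude=1.0):
    """Ideal rotational flow field (counter-clockwise) around a pixel."""
    u, v = radial_source_field(shape, center, magnitude)
    return -v, u


def smooth_random_field(rng, shape=(24, 24), n_modes=4, amplitude=1.0):
    """Band-limited random 2-D vector field, periodic on the row axis
    (the detector's domain wraps circumferentially)."""
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    u = np.zeros(shape)
    v = np.zeros(shape)
    for _ in range(n_modes):
        m = rng.integers(-2, 3)
        kr = 2 * np.pi * m / shape[0]
        kc = rng.uniform(-0.5, 0.5)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        a1, a2 = rng.normal(0, amplitude, size=2)
        u += a1 * np.sin(kr * r + kc * c + ph1)
        v += a2 * np.sin(kr * r + kc * c + ph2)
    return u, v
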