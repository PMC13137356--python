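import numpy as np
import pytest

from cervixnet.config import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def ramp32():
    """Smooth 32x32 gradient image: impulse-free, locally near-linear."""
    y, x = np.mgrid[:32, :32].astype(np.float64)
    return np.rint(60 + 2.0 * x + 1.0 * y).astype(np.uint8)


def grating(size, orientation_deg, wavelength=8.0, amplitude=60.0, base=128.0):
    """Sinusoidal grating; wave vector at ``orientation_deg`` (x=cols, y=rows-down)."""
    h, w = size
    yy, xx = np.mgrid[:h, :w].astype(np.float64)
    th = np.deg2rad(orientation_deg)
    return base + amplitude * np.sin(2 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / wavelength)
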