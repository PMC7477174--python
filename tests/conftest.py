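import numpy as np
import pytest

from ovifnirs.invert import ExtinctionMatrix
from ovifnirs.media import LayeredMedium, OpticalProperties, ProbeConfig

WAVELENGTHS = (751.0, 839.0)


@pytest.fixture(scope="session")
def baseline_props():
    """Baseline head optical properties per wavelength (config defaults)."""
    return {wl: OpticalProperties(0.015, 1.0, wl) for wl in WAVELENGTHS}


@pytest.fixture(scope="session")
def baseline_medium(baseline_props):
    """Sheep-like two-layer head: 10 mm extra-cerebral slab over cortex."""
    return LayeredMedium(10.0, baseline_props, baseline_props, 1.4, 1.0)


@pytest.fixture(scope="session")
def probe():
    return ProbeConfig()


@pytest.fixture(scope="session")
def sheep_eps():
    return ExtinctionMatrix()


@pytest.fixture(scope="session")
def matched_props():
    """Single-wavelength matched-boundary medium for oracle comparisons."""
    return OpticalProperties(0.01, 1.0)
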