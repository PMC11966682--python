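"""Shared fixtures: preset species, instrument settings, small synthetic targets."""

import numpy as np
import pytest

from fesepr import (
    GTensor,
    InstrumentConfig,
    SpeciesModel,
    instrument_presets,
    preset_library,
)


@pytest.fixture(scope="session")
def presets():
    return preset_library()


@pytest.fixture(scope="session")
def x_band():
    return instrument_presets()["x_band"]


@pytest.fixture(scope="session")
def q_band():
    return instrument_presets()["q_band"]


@pytest.fixture(scope="session")
def x_band_abs(x_band):
    return x_band.replace(detection_mode="absorption")


@pytest.fixture(scope="session")
def q_band_abs(q_band):
    return q_band.replace(detection_mode="absorption")


@pytest.fixture(scope="session")
def axial_species(presets):
    return presets["axial-A"]


@pytest.fixture(scope="session")
def rhombic_species(presets):
    return presets["rhombic-R"]


@pytest.fixture
def narrow_species():
    """Small-strain species for tests needing sharp spectral features."""
    return SpeciesModel(name="narrow", g=GTensor(2.045, 1.926, 1.896),
                        g_strain=(0.002, 0.002, 0.002), residual_linewidth=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
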