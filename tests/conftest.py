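import numpy as np
import pytest

from acoustotrap import (
    POLYSTYRENE_BEAD,
    WATER,
    PiezoResponse,
    ResonatorCavity,
    tune_height,
)


@pytest.fixture
def water():
    return WATER


@pytest.fixture
def bead():
    return POLYSTYRENE_BEAD


@pytest.fixture
def quiet_piezo():
    """Noiseless piezo response: dip location is exact."""
    return PiezoResponse(baseline=2.0, dip_depth=0.5, noise_sigma=0.0)


@pytest.fixture
def noisy_piezo():
    """1% of baseline per-sample voltage noise."""
    return PiezoResponse(baseline=2.0, dip_depth=0.5, noise_sigma=0.02)


def cavity_at(frequency_hz, medium=WATER, quality=1000.0, pressure=0.5e6):
    """Cavity whose fundamental sits at frequency_hz in the given medium."""
    return ResonatorCavity(
        height=tune_height(frequency_hz, medium),
        quality_factor=quality,
        peak_pressure=pressure,
    )


@pytest.fixture
def cavity_758(water):
    return cavity_at(7.58e6, water)
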