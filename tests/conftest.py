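import numpy as np
import pytest

from microcolony.geometry import IlluminationSource, ScanSchedule, SensorSpec, design_scan
from microcolony.phantom import ColonySeed, GrowthModel, NoiseParams, PlatePhantom


@pytest.fixture
def small_sensor() -> SensorSpec:
    """A 96×96-pixel crop of the 2.2-μm-pitch sensor (211 μm square FOV)."""
    return SensorSpec(pixel_pitch_um=2.2, width_px=96, height_px=96)


@pytest.fixture
def onaxis() -> IlluminationSource:
    return IlluminationSource(offset_mm=(0.0, 0.0), height_mm=80.0)


@pytest.fixture
def onaxis_schedule(onaxis) -> ScanSchedule:
    return ScanSchedule((onaxis,))


@pytest.fixture
def sweep_schedule(small_sensor) -> ScanSchedule:
    """Designed 8×8 sub-pixel sweep for E=4 at z = 5 μm."""
    return design_scan(small_sensor, 5.0, enhancement=4, grid_n=8, height_mm=80.0)


@pytest.fixture
def single_colony_phantom(small_sensor) -> PlatePhantom:
    """One colony (lag 0, v = 0.1 μm/min) near the centre of the small sensor."""
    growth = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.1, seed_diameter_um=1.0)
    centre = 48 * small_sensor.pixel_pitch_um
    return PlatePhantom(
        sensor=small_sensor,
        colonies=(ColonySeed(x_um=centre + 0.8, y_um=centre - 0.5, growth=growth),),
        z_um=5.0,
        seed=11,
    )


@pytest.fixture
def noiseless() -> NoiseParams:
    return NoiseParams.noiseless()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
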