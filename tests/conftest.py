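import numpy as np
import pytest

from slotsim import AcquisitionGeometry, ScenarioConfig


@pytest.fixture
def tiny_config() -> ScenarioConfig:
    """A fast scenario: short implant, coarse grid, five time points."""
    return ScenarioConfig(
        grid_shape=(32, 32, 64),
        voxel_pitch=0.15,
        implant_length=9.6,
        implant_radius=1.5,
        time_points=(0.0, 7.0, 14.0, 21.0, 28.0),
        front_velocity=0.2,
        cell_surface_density=300.0,
        rng_seed=1,
    )


@pytest.fixture
def tiny_geometry(tiny_config) -> AcquisitionGeometry:
    return AcquisitionGeometry.for_scenario(tiny_config, n_angles=40)


@pytest.fixture
def disc_slice():
    """Centered uniform unit disc on a 128² grid (inscribed-circle content)."""
    width, radius = 128, 30
    center = (width - 1) / 2
    yy, xx = np.mgrid[0:width, 0:width]
    return ((xx - center) ** 2 + (yy - center) ** 2 <= radius**2).astype(float), radius
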