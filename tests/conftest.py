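import numpy as np
import pytest

from skullbeam import pipeline
from skullbeam.acoustics import water_medium
from skullbeam.phantoms import PhantomSpec, generate_skull_phantom


@pytest.fixture(scope="session")
def desk64():
    """Reduced-scale setup: 64x64 over 6 cm, 16 elements, 250 kHz."""
    return pipeline.desk_setup(64)


@pytest.fixture(scope="session")
def desk32():
    """Coarse setup for surrogate training: 32x32, 16 elements, 150 kHz."""
    return pipeline.desk_setup(32)


@pytest.fixture(scope="session")
def phantom64(desk64):
    spec, _, _ = desk64
    return generate_skull_phantom(spec, seed=3)


@pytest.fixture(scope="session")
def water64(desk64):
    _, _, config = desk64
    return water_medium(64, config.pixel_spacing_mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fixed_phantom_spec():
    """Degenerate ranges: every geometric parameter known exactly."""
    return PhantomSpec(
        grid_size_native=64,
        pixel_spacing_mm=0.9375,
        curvature_radius_mm=(80.0, 80.0),
        total_thickness_mm=(6.0, 6.0),
        cortical_fraction=(0.3, 0.3),
        cortical_hu=(1500.0, 1500.0),
        trabecular_hu=(500.0, 500.0),
        trabecular_noise_scale=0.0,
        apex_depth_mm=(10.0, 10.0),
        center_col_jitter_mm=0.0,
    )
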