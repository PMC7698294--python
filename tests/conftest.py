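import numpy as np
import pytest

from fibermatrix import FiberPopulationSpec, SimConfig


@pytest.fixture
def narrow_population():
    """Monodisperse 2 µm ribbons, rigid."""
    return FiberPopulationSpec(
        width_range_um=(2.0, 2.0),
        aspect_ratio=10.0,
        wall_thickness_um=0.25,
        flexibility=0,
    )


@pytest.fixture
def measured_range_population():
    return FiberPopulationSpec(
        width_range_um=(0.0685, 9.8),
        width_law="log-uniform",
        aspect_ratio=15.0,
        wall_thickness_um=0.3,
        flexibility=0,
    )


@pytest.fixture
def tiny_config(narrow_population):
    return SimConfig(
        domain_px=(32, 32),
        resolution_um_per_voxel=0.5,
        target_layers=1.5,
        population=narrow_population,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
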