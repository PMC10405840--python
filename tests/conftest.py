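import numpy as np
import pytest

from sonoquant import (
    ConfocalFieldSpec,
    MRPhantomSpec,
    grid_plaques,
    make_confocal_field,
    make_mr_phantom,
    single_process_field,
)

# per-cell process lengths (μm, center-to-endpoint) of the two reference
# phantoms: 20 evenly spaced cells plus one long outlier each
SONICATED_LENGTHS = [145.0 + 25.0 * k for k in range(20)] + [900.0]
SHAM_LENGTHS = [200.0 + 50.0 * k for k in range(20)] + [1400.0]


def full_image_polygon(shape):
    return [(0, 0), (0, shape[1] - 1), (shape[0] - 1, shape[1] - 1), (shape[0] - 1, 0)]


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """Sphere of radius 2.3945 mm rasterized at 0.1 mm (fast unit-test grid)."""
    spec = MRPhantomSpec(
        grid_shape=(80, 80, 80),
        voxel_size=(0.1, 0.1, 0.1),
        opening_center=(4.0, 4.0, 4.0),
        opening_semi_axes=(2.3945, 2.3945, 2.3945),
        reference_box=((0, 0, 0), (12, 12, 12)),
    )
    vol, truth = make_mr_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def sonicated_field():
    spec = single_process_field(SONICATED_LENGTHS, seed=11)
    vol, truth = make_confocal_field(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def sham_field():
    spec = single_process_field(SHAM_LENGTHS, seed=12)
    vol, truth = make_confocal_field(spec)
    return spec, vol, truth


def plaque_field(n_plaques: int, radius_px: float = 4.0, seed: int = 3):
    shape = (max(60, 18 * int(np.ceil(n_plaques / 13)) + 60), 260)
    spec = ConfocalFieldSpec(
        image_shape=shape,
        pixel_size=1.0,
        plaques=grid_plaques(n_plaques, radius_px, shape),
        n_scatter_nuclei=0,
        seed=seed,
    )
    return make_confocal_field(spec)
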