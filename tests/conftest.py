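import numpy as np
import pytest

from ict.phantom import PhantomSpec, generate_phantom
from ict.segmentation import assign_wall, binarize_otsu, classify_cells, \
    segment_lumens


@pytest.fixture(scope="session")
def tiny_spec():
    """Small but anatomically complete phantom spec (one EW->LW ring)."""
    return PhantomSpec(volume_shape=(144, 144, 160), seed=3)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, blur-free two-phase phantom (hard voxel rendering)."""
    spec = PhantomSpec(volume_shape=(144, 144, 128), seed=1,
                       noise_sd=0.0, blur_fwhm=0.0)
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def segmented_tiny(tiny_phantom):
    vol, gt = tiny_phantom
    binv = binarize_otsu(vol)
    lv = segment_lumens(binv)
    lv = classify_cells(lv)
    lv = assign_wall(lv, binv)
    return vol, gt, binv, lv


def make_tube_volume(shape=(64, 64, 96), radius_px=9.0, axis=2,
                     center=None, voxel=1.62):
    """A single straight tube of air in a wall block (uint8, no blur)."""
    from ict.phantom import GrayVolume

    data = np.full(shape, 190, dtype=np.uint8)
    if center is None:
        center = (shape[0] / 2 - 0.37, shape[1] / 2 + 0.21)
    idx = [np.arange(s, dtype=float) for s in shape]
    if axis == 2:
        rho2 = (idx[0][:, None, None] - center[0]) ** 2 \
            + (idx[1][None, :, None] - center[1]) ** 2
        mask = np.broadcast_to(rho2 <= radius_px**2, shape)
    else:
        rho2 = (idx[1][None, :, None] - center[0]) ** 2 \
            + (idx[2][None, None, :] - center[1]) ** 2
        mask = np.broadcast_to(rho2 <= radius_px**2, shape)
    data = data.copy()
    data[mask] = 60
    return GrayVolume(data, voxel), mask
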