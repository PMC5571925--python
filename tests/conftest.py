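import numpy as np
import pytest

from petsarc import LesionMask, PhantomSpec, SuvVolume, generate_phantom


def digital_sphere_mask(radius_vox: int, spacing=(1.0, 1.0, 1.0)) -> LesionMask:
    """Binary sphere of the given radius (in voxels) with a 2-voxel margin."""
    n = 2 * radius_vox + 5
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n))
    d2 = sum((ix - c) ** 2 for ix in idx)
    return LesionMask(d2 <= radius_vox**2, spacing)


@pytest.fixture
def sphere_phantom():
    """Noise-free uniform sphere lesion (SUV 8) on background 1, contrast 8:1."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing=(2.0, 2.0, 2.0),
        semi_axes=(12.0, 12.0, 12.0),
        lesion_suv=8.0,
        background_suv=1.0,
        noise_sd=0.0,
        background_noise_sd=0.0,
        seed=42,
    )
    vol, mask = generate_phantom(spec)
    return spec, vol, mask


def random_quantized(rng, shape=(4, 4, 4), n_levels=4, mask_p=0.8):
    """Random small level grid + mask, as (levels, mask) arrays."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[0, 0, 0] = True
    levels = np.where(mask, rng.integers(1, n_levels + 1, shape), 0).astype(np.int32)
    return levels, mask


def quantized_from_arrays(levels, mask, n_levels):
    from petsarc.texture import QuantizedVolume

    return QuantizedVolume(
        levels.astype(np.int32), mask.astype(bool), n_levels, 0.0, float(n_levels)
    )


def volume_from_levels(levels, mask, spacing=(1.0, 1.0, 1.0)):
    """SuvVolume whose masked min-max quantization reproduces `levels` exactly."""
    vals = np.where(mask, levels.astype(float), 0.0)
    return SuvVolume(vals, spacing), LesionMask(mask, spacing)
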