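"""SUV-based intensity and volume metrics, and between-timepoint deltas.

All metrics operate on a :class:`SuvVolume` restricted to a :class:`LesionMask`:

* SUVmax — maximum voxel SUV inside the VOI.
* SUVmean — arithmetic mean SUV inside the VOI.
* SUVpeak — maximum, over candidate centers, of the mean SUV inside a fixed
  1-cm^3 sphere (radius ~6.204 mm); the sphere itself is not restricted to
  the VOI.
* MTV — metabolically active volume: foreground voxels x voxel volume, in mL.
* TLG — SUVmean x MTV.

Percent changes between baseline and post-chemotherapy studies use
100 * (post - pre) / pre with the sign preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volumes import LesionMask, SuvVolume

#: radius (mm) of the sphere with volume 1 cm^3
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

#: features differenced by :func:`delta_percent`
DELTA_FEATURES = ("suv_max", "suv_peak", "suv_mean", "tlg", "mtv")


def _check_mask(vol: SuvVolume, mask: LesionMask) -> None:
    mask.check_companion(vol)
    if mask.n_voxels == 0:
        raise ValueError("empty lesion mask")


def suv_basic(vol: SuvVolume, mask: LesionMask) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the VOI."""
    _check_mask(vol, mask)
    vals = vol.values[mask.values]
    return float(vals.max()), float(vals.mean())


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    if all(h == 0 for h in half):
        raise ValueError(
            f"voxel spacing {spacing} mm too coarse: the {radius_mm:.3f} mm sphere "
            "contains no neighbouring voxel centers"
        )
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    return (d2 <= radius_mm**2).astype(np.float64)


def suv_peak(
    vol: SuvVolume,
    mask: LesionMask,
    mode: str = "max_mean",
    radius_mm: float = PEAK_SPHERE_RADIUS_MM,
) -> float:
    """SUVpeak: spherical-mean SUV at the highest-uptake part of the lesion.

    mode ``"max_mean"`` (default) maximizes the sphere mean over every
    candidate center in the VOI; ``"at_max"`` fixes the sphere at the SUVmax
    voxel. The sphere mean averages all voxels whose centers lie within
    ``radius_mm`` of the candidate center, whether or not they are in the VOI.
    """
    _check_mask(vol, mask)
    kernel = _sphere_kernel(vol.spacing, radius_mm)
    # near the grid boundary the sphere is truncated: average only over the
    # voxel centers that exist, so the mean matches direct enumeration
    num = ndimage.convolve(vol.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(vol.values), kernel, mode="constant", cval=0.0)
    means = num / den
    if mode == "max_mean":
        return float(means[mask.values].max())
    if mode == "at_max":
        flat = np.where(mask.values, vol.values, -np.inf)
        center = np.unravel_index(int(flat.argmax()), vol.values.shape)
        return float(means[center])
    raise ValueError(f"unknown SUVpeak mode {mode!r}")


def mtv_tlg(
    vol: SuvVolume, mask: LesionMask, allow_empty: bool = False
) -> tuple[float, float]:
    """(MTV in mL, TLG in mL*SUV).

    An empty mask is an error unless ``allow_empty`` is set (post-therapy
    fallback VOIs with no residual uptake), in which case both are 0.
    """
    mask.check_companion(vol)
    n = mask.n_voxels
    if n == 0:
        if allow_empty:
            return 0.0, 0.0
        raise ValueError("empty lesion mask")
    mtv = n * mask.voxel_volume_mm3 / 1000.0
    tlg = float(vol.values[mask.values].mean()) * mtv
    return mtv, tlg


def delta_percent(
    pre: dict[str, float],
    post: dict[str, float],
    features: tuple[str, ...] = DELTA_FEATURES,
) -> dict[str, float]:
    """Signed percent change per feature: 100 * (post - pre) / pre.

    A non-positive or missing baseline value leaves that delta as NaN with a
    warning (the change is undefined relative to a zero baseline).
    """
    out: dict[str, float] = {}
    for f in features:
        p0 = pre.get(f)
        p1 = post.get(f)
        if p0 is None or p1 is None or not np.isfinite(p0) or p0 <= 0:
            warnings.warn(f"delta of {f!r} undefined (baseline {p0!r}); recorded as missing")
            out[f] = float("nan")
        else:
            out[f] = 100.0 * (p1 - p0) / p0
    return out
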