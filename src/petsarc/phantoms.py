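"""Synthetic PET phantoms: FDG-avid ellipsoidal lesions on a low-uptake background.

Every downstream stage of the pipeline (segmentation, intensity, texture,
shape, response) is exercised on these phantoms, for which the ground-truth
mask and intensity pattern are known exactly.

Conventions
-----------
* Lesion membership is decided by the voxel-center test: a voxel belongs to
  the lesion iff its center lies inside the ellipsoid. No partial-volume
  weighting is applied.
* ``lesion_suv`` is the peak lesion SUV of the noise-free pattern; texture
  patterns modulate downward from it.
* Noise is additive Gaussian, clipped at zero (SUV images are non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .volumes import LesionMask, SuvVolume, save_volume

TEXTURE_KINDS = ("uniform", "gradient", "checkerboard", "blobs")


@dataclass(frozen=True)
class Texture:
    """Intensity pattern painted inside the lesion.

    kind:
        ``uniform``       constant ``lesion_suv``.
        ``gradient``      linear ramp along axis 0, from 0.5x to 1x
                          ``lesion_suv`` across the lesion extent.
        ``checkerboard``  two SUV levels (``lesion_suv`` and
                          ``lesion_suv - amplitude``) alternating in blocks of
                          ``period`` voxels; hand-computable texture matrices.
        ``blobs``         ``count`` Gaussian hot spots of height ``amplitude``
                          over a base of ``lesion_suv - amplitude``.
    """

    kind: str = "uniform"
    period: int = 2
    count: int = 5
    amplitude: float | None = None  # default: half the lesion/background contrast

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ValueError(f"texture kind must be one of {TEXTURE_KINDS}")
        if self.period < 1:
            raise ValueError("checkerboard period must be >= 1 voxel")
        if self.count < 1:
            raise ValueError("blob count must be >= 1")


@dataclass
class PhantomSpec:
    """Full description of one synthetic PET study.

    ``seed`` fixes every random draw: identical specs give bit-identical
    volumes.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    background_noise_sd: float = 0.05
    lesion_center: tuple[float, float, float] | None = None  # voxel coords; default grid center
    semi_axes: tuple[float, float, float] = (20.0, 14.0, 14.0)  # mm
    lesion_suv: float = 8.0
    texture: Texture = field(default_factory=Texture)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must all be > 0")
        if self.lesion_suv <= self.background_suv:
            raise ValueError("lesion_suv must exceed background_suv (positive contrast)")
        if self.background_noise_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid must have >= 1 voxel per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.lesion_center is None:
            self.lesion_center = tuple((n - 1) / 2.0 for n in self.grid_shape)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["texture"] = asdict(self.texture)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "texture" in d and isinstance(d["texture"], dict):
            d["texture"] = Texture(**d["texture"])
        for key in ("grid_shape", "spacing", "semi_axes", "lesion_center"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxel-center membership test against the ellipsoid, with bounds check."""
    axes_mm = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    center_mm = [c * s for c, s in zip(spec.lesion_center, spec.spacing)]
    for ax, (c, a, n, s) in enumerate(
        zip(center_mm, spec.semi_axes, spec.grid_shape, spec.spacing)
    ):
        if c - a < 0 or c + a > (n - 1) * s:
            raise ValueError(
                f"lesion extends outside the grid along axis {ax}: "
                f"center {c:.1f} mm, semi-axis {a:.1f} mm, grid extent {(n - 1) * s:.1f} mm"
            )
    xs = [(axm - c) / a for axm, c, a in zip(axes_mm, center_mm, spec.semi_axes)]
    d2 = (
        xs[0][:, None, None] ** 2
        + xs[1][None, :, None] ** 2
        + xs[2][None, None, :] ** 2
    )
    return d2 <= 1.0


def _lesion_pattern(spec: PhantomSpec, inside: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Noise-free lesion SUV at every in-lesion voxel (full-grid array)."""
    tx = spec.texture
    amp = tx.amplitude
    if amp is None:
        amp = 0.5 * (spec.lesion_suv - spec.background_suv)
    out = np.full(spec.grid_shape, spec.lesion_suv, dtype=np.float64)
    if tx.kind == "uniform":
        return out
    if tx.kind == "gradient":
        idx0 = np.nonzero(inside.any(axis=(1, 2)))[0]
        lo, hi = idx0.min(), idx0.max()
        t = np.zeros(spec.grid_shape[0]) if hi == lo else (np.arange(spec.grid_shape[0]) - lo) / (hi - lo)
        ramp = spec.lesion_suv * (0.5 + 0.5 * np.clip(t, 0, 1))
        out[:] = ramp[:, None, None]
        return out
    if tx.kind == "checkerboard":
        grids = np.meshgrid(*[np.arange(n) // tx.period for n in spec.grid_shape], indexing="ij")
        parity = (grids[0] + grids[1] + grids[2]) % 2
        out[parity == 1] = spec.lesion_suv - amp
        return out
    # blobs: Gaussian hot spots on a lowered base
    out[:] = spec.lesion_suv - amp
    coords = np.argwhere(inside)
    sigma_vox = max(min(spec.semi_axes) / (4.0 * max(spec.spacing)), 0.8)
    centers = coords[rng.integers(0, len(coords), size=tx.count)]
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
    for c in centers:
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        out += amp * np.exp(-d2 / (2 * sigma_vox**2))
    np.minimum(out, spec.lesion_suv, out=out)
    return out


def _paint(spec: PhantomSpec, uptake_scale: float, timepoint: str) -> tuple[SuvVolume, LesionMask]:
    rng = np.random.default_rng(spec.seed)
    inside = _ellipsoid_mask(spec)
    pattern = _lesion_pattern(spec, inside, rng)
    values = spec.background_suv + rng.normal(0.0, spec.background_noise_sd, spec.grid_shape)
    lesion_vals = np.maximum(pattern[inside] * uptake_scale, spec.background_suv)
    lesion_vals = lesion_vals + rng.normal(0.0, spec.noise_sd, lesion_vals.shape)
    values[inside] = lesion_vals
    np.clip(values, 0.0, None, out=values)
    return (
        SuvVolume(values, spec.spacing, timepoint),
        LesionMask(inside, spec.spacing),
    )


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, LesionMask]:
    """Render the phantom described by ``spec`` with its ground-truth mask."""
    return _paint(spec, 1.0, "baseline")


def generate_response_pair(
    spec: PhantomSpec, uptake_scale: float, volume_scale: float = 1.0
) -> tuple[tuple[SuvVolume, LesionMask], tuple[SuvVolume, LesionMask]]:
    """Paired baseline / post-chemotherapy studies of the same lesion.

    The post-therapy lesion has its uptake multiplied by ``uptake_scale``
    (never dropping below the background level, so ``uptake_scale = 0``
    makes the lesion vanish into the background) and its semi-axes scaled by
    ``volume_scale ** (1/3)`` so the lesion volume scales by ``volume_scale``.

    The post study uses an independent noise stream derived from the same
    seed, so the pair is reproducible as a unit.
    """
    if uptake_scale < 0 or volume_scale < 0:
        raise ValueError("uptake_scale and volume_scale must be >= 0")
    baseline = _paint(spec, 1.0, "baseline")
    s = volume_scale ** (1.0 / 3.0)
    post_spec = PhantomSpec(
        grid_shape=spec.grid_shape,
        spacing=spec.spacing,
        background_suv=spec.background_suv,
        background_noise_sd=spec.background_noise_sd,
        lesion_center=spec.lesion_center,
        semi_axes=tuple(max(a * s, 1e-9) for a in spec.semi_axes),
        lesion_suv=spec.lesion_suv,
        texture=spec.texture,
        noise_sd=spec.noise_sd,
        seed=spec.seed + 1,
    )
    post = _paint(post_spec, uptake_scale, "post_cht")
    return baseline, post


def save_phantom(
    vol: SuvVolume, mask: LesionMask, image_path: str | Path, mask_path: str | Path
) -> None:
    """Write an image + mask pair as NIfTI."""
    save_volume(vol, image_path)
    save_volume(mask, mask_path)
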