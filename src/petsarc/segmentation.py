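"""Lesion delineation by iterative adaptive thresholding.

The threshold is contrast-adaptive: starting from a fraction of the local
SUVmax, it is re-estimated from the current region as

    T_{k+1} = alpha * mean(SUV inside region_k) + beta * background

where region_k is the connected component above T_k containing the seed.
Iteration stops when the relative threshold change falls below ``tol``.

When nothing around the seed rises above the initial threshold (typical for a
post-chemotherapy lesion with complete metabolic response), the lesion is
declared non-delineable and the caller should fall back to reproducing the
baseline VOI (:func:`fallback_voi`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LesionMask, SuvVolume

_STRUCTURES = {6: 1, 18: 2, 26: 3}


class LesionNotDelineableError(RuntimeError):
    """No uptake above the initial threshold around the seed."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the adaptive threshold scheme.

    alpha : weight of the current region mean in the threshold update (0, 1].
    beta : weight of the background term.
    t0_fraction : initial threshold as a fraction of the local SUVmax, (0, 1).
    tol : relative convergence tolerance on the threshold.
    max_iter : iteration cap.
    connectivity : 6, 18 or 26 neighbourhood for the connected component.
    """

    alpha: float = 0.5
    beta: float = 1.0
    t0_fraction: float = 0.4
    tol: float = 0.01
    max_iter: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.t0_fraction < 1):
            raise ValueError("t0_fraction must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class SegmentationResult:
    mask: LesionMask
    threshold: float
    converged: bool
    n_iter: int


def _seed_component(above: np.ndarray, seed: tuple[int, int, int], structure: np.ndarray) -> np.ndarray | None:
    """Connected component of ``above`` containing (or adjacent to) the seed."""
    labels, _ = ndimage.label(above, structure=structure)
    lab = labels[seed]
    if lab == 0:
        # tolerate a seed placed one voxel off a hot spot
        lo = tuple(max(s - 1, 0) for s in seed)
        hi = tuple(min(s + 2, n) for s, n in zip(seed, labels.shape))
        window = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        nz = window[window > 0]
        if nz.size == 0:
            return None
        lab = int(np.bincount(nz).argmax())
    return labels == lab


def adaptive_segment(
    vol: SuvVolume,
    seed_voxel: tuple[int, int, int],
    background: float,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Delineate the lesion containing ``seed_voxel``.

    Raises
    ------
    LesionNotDelineableError
        if no voxel connected to the seed exceeds the initial threshold, or
        the region empties during iteration.
    """
    params = params or SegmentationParams()
    seed = tuple(int(s) for s in seed_voxel)
    if any(s < 0 or s >= n for s, n in zip(seed, vol.values.shape)):
        raise ValueError(f"seed voxel {seed} outside grid {vol.values.shape}")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[params.connectivity])

    lo = tuple(max(s - 1, 0) for s in seed)
    hi = tuple(min(s + 2, n) for s, n in zip(seed, vol.values.shape))
    local_max = float(vol.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].max())
    t = params.t0_fraction * local_max

    region = _seed_component(vol.values > t, seed, structure)
    if region is None:
        raise LesionNotDelineableError(f"no voxel above initial threshold {t:.3g} at seed {seed}")

    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        t_new = params.alpha * float(vol.values[region].mean()) + params.beta * background
        new_region = _seed_component(vol.values > t_new, seed, structure)
        if new_region is None:
            raise LesionNotDelineableError(
                f"region emptied at threshold {t_new:.3g} (iteration {n_iter}); lesion not delineable"
            )
        if abs(t_new - t) / t < params.tol:
            t, region = t_new, new_region
            converged = True
            break
        t, region = t_new, new_region

    return SegmentationResult(
        mask=LesionMask(region, vol.spacing),
        threshold=float(t),
        converged=converged,
        n_iter=n_iter,
    )


def fallback_voi(
    baseline_mask: LesionMask,
    post_vol: SuvVolume,
    offset: tuple[int, int, int] = (0, 0, 0),
) -> LesionMask:
    """Reproduce the baseline VOI on the post-therapy grid.

    The caller supplies the landmark alignment as a rigid voxel translation;
    the mask volume is preserved exactly.
    """
    if baseline_mask.values.shape != post_vol.values.shape:
        raise ValueError("baseline mask and post volume grids differ in shape")
    coords = np.argwhere(baseline_mask.values)
    if coords.size == 0:
        raise ValueError("baseline mask is empty")
    shifted = coords + np.asarray(offset, dtype=int)
    if (shifted < 0).any() or (shifted >= np.array(post_vol.values.shape)).any():
        raise ValueError(f"translation {tuple(offset)} pushes the VOI outside the grid")
    out = np.zeros_like(baseline_mask.values)
    out[tuple(shifted.T)] = True
    return LesionMask(out, post_vol.spacing)
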