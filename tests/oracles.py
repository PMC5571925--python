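"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nested loops / BFS over voxels, with no
code shared with the package internals.
"""

from __future__ import annotations

from collections import deque

import numpy as np

ALL_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Ordered-pair enumeration at the 13 offsets, symmetrized, normalized."""
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in HALF_13:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        i, j = levels[x, y, z] - 1, levels[u, v, w] - 1
                        counts[i, j] += 1
                        counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def glrlm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run scan: walk every grid line in each of the 13 directions."""
    shape = levels.shape
    max_len = max(shape)
    counts = np.zeros((n_levels, max_len))
    for d in HALF_13:
        d = np.array(d)
        # starting voxels: those whose predecessor along d is outside the grid
        for start in np.ndindex(shape):
            prev = np.array(start) - d
            if ((prev >= 0) & (prev < shape)).all():
                continue
            # walk the full line, splitting runs on mask gaps / level changes
            pos = np.array(start)
            run_level, run_len = None, 0
            while ((pos >= 0) & (pos < shape)).all():
                p = tuple(pos)
                if mask[p]:
                    if levels[p] == run_level:
                        run_len += 1
                    else:
                        if run_level is not None:
                            counts[run_level - 1, run_len - 1] += 1
                        run_level, run_len = levels[p], 1
                else:
                    if run_level is not None:
                        counts[run_level - 1, run_len - 1] += 1
                    run_level, run_len = None, 0
                pos = pos + d
            if run_level is not None:
                counts[run_level - 1, run_len - 1] += 1
    return counts


def glszm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Flood-fill (BFS, 26-connected) zones of constant level within the mask."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        lev = levels[start]
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            size += 1
            for d in ALL_26:
                q = tuple(np.array(p) + d)
                if all(0 <= qi < si for qi, si in zip(q, shape)):
                    if mask[q] and not seen[q] and levels[q] == lev:
                        seen[q] = True
                        queue.append(q)
        zones.append((int(lev), size))
    max_size = max(s for _, s in zones)
    counts = np.zeros((n_levels, max_size))
    for lev, size in zones:
        counts[lev - 1, size - 1] += 1
    return counts


def suv_peak_bruteforce(
    values: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    radius_mm: float,
) -> float:
    """Max over in-mask centers of the mean over voxel centers within radius."""
    sp = np.asarray(spacing, float)
    all_coords = np.argwhere(np.ones_like(values, dtype=bool))  # every voxel center
    flat = values.ravel()
    best = -np.inf
    for c in np.argwhere(mask):
        d2 = (((all_coords - c) * sp) ** 2).sum(axis=1)
        inside = d2 <= radius_mm**2
        best = max(best, float(flat[inside].mean()))
    return float(best)
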