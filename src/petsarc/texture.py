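"""3-D texture matrices and heterogeneity features on a quantized VOI.

The masked SUV values are resampled to G grey levels (default 64) by masked
min-max quantization. Three matrices are built over the VOI:

* GLCM — grey-level co-occurrence: voxel pairs at one-voxel displacement
  along the 13 unique 3-D directions, aggregated into a single symmetric
  matrix and normalized to probabilities.
* GLRLM — grey-level run lengths: maximal constant-level runs along the same
  13 directions, one aggregated matrix; a gap in the mask breaks a run.
* GLSZM — grey-level size zones: maximal 26-connected constant-level zones
  within the mask (direction-free).

Features: GLCM homogeneity / entropy (bits) / dissimilarity, GLRLM high
grey-level run emphasis (HGRE), GLSZM zone (size-)length non-uniformity
(ZLNU) and short-zone high grey-level emphasis (SZHGE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LesionMask, SuvVolume

#: the 13 unique one-voxel displacements (lexicographically positive half of
#: the 26-neighbourhood; opposite directions are equivalent for pair and run
#: counting)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)


@dataclass
class QuantizedVolume:
    """Grey-level grid on the VOI; 0 is the out-of-mask sentinel."""

    levels: np.ndarray  # int array, 0 outside mask, 1..G inside
    mask: np.ndarray  # bool
    n_levels: int
    suv_min: float
    suv_max: float

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray  # G x G, symmetric
    probabilities: np.ndarray  # normalized


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # G x Lmax, counts[i-1, l-1] = r(i, l)

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())


@dataclass
class SizeZoneMatrix:
    counts: np.ndarray  # G x Smax, counts[i-1, s-1] = z(i, s)

    @property
    def n_zones(self) -> float:
        return float(self.counts.sum())


def quantize(vol: SuvVolume, mask: LesionMask, n_levels: int = 64) -> QuantizedVolume:
    """Masked min-max quantization to ``n_levels`` grey levels.

    level(v) = min(G, floor(G * (v - min) / (max - min)) + 1); a constant
    region maps entirely to level 1. Any positive affine transform of the raw
    SUV values leaves the levels unchanged.
    """
    mask.check_companion(vol)
    if mask.n_voxels == 0:
        raise ValueError("empty lesion mask")
    if n_levels < 2:
        raise ValueError("need at least 2 grey levels")
    vals = vol.values[mask.values]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.values] = 1
    else:
        scaled = np.floor(n_levels * (vals - vmin) / (vmax - vmin)).astype(np.int32) + 1
        levels[mask.values] = np.minimum(scaled, n_levels)
    return QuantizedVolume(levels, mask.values.copy(), n_levels, vmin, vmax)


def build_glcm(q: QuantizedVolume) -> CooccurrenceMatrix:
    """Symmetric co-occurrence matrix over the 13 directions, normalized once."""
    g = q.n_levels
    counts = np.zeros((g, g), dtype=np.float64)
    lev, msk = q.levels, q.mask
    for d in DIRECTIONS_13:
        src = tuple(
            slice(max(-o, 0), n - max(o, 0)) for o, n in zip(d, lev.shape)
        )
        dst = tuple(
            slice(max(o, 0), n - max(-o, 0)) for o, n in zip(d, lev.shape)
        )
        valid = msk[src] & msk[dst]
        a = lev[src][valid] - 1
        b = lev[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no voxel pairs: mask has < 2 voxels along every direction")
    return CooccurrenceMatrix(counts=counts, probabilities=counts / total)


def glcm_features(m: CooccurrenceMatrix) -> tuple[float, float, float]:
    """(homogeneity, entropy in bits, dissimilarity) of a normalized GLCM."""
    p = m.probabilities
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("co-occurrence matrix is not normalized")
    g = p.shape[0]
    i, j = np.indices((g, g))
    absdiff = np.abs(i - j)
    homogeneity = float((p / (1.0 + absdiff)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    dissimilarity = float((absdiff * p).sum())
    return homogeneity, entropy, dissimilarity


def build_glrlm(q: QuantizedVolume) -> RunLengthMatrix:
    """Run-length matrix aggregated over the 13 directions.

    A run is a maximal streak of equal grey level along one direction, broken
    by the mask boundary or the grid edge.
    """
    if q.n_masked == 0:
        raise ValueError("empty lesion mask")
    lev, msk = q.levels, q.mask
    shape = np.array(lev.shape)
    max_len = int(shape.max())
    counts = np.zeros((q.n_levels, max_len), dtype=np.float64)
    coords_all = np.argwhere(msk)
    for d in DIRECTIONS_13:
        dvec = np.array(d)
        prev = coords_all - dvec
        in_grid = ((prev >= 0) & (prev < shape)).all(axis=1)
        starts = np.ones(len(coords_all), dtype=bool)
        pi = tuple(prev[in_grid].T)
        same_prev = msk[pi] & (lev[pi] == lev[tuple(coords_all[in_grid].T)])
        starts[in_grid] = ~same_prev
        cur = coords_all[starts]
        run_level = lev[tuple(cur.T)]
        length = np.ones(len(cur), dtype=np.int64)
        while len(cur):
            nxt = cur + dvec
            ok = ((nxt >= 0) & (nxt < shape)).all(axis=1)
            cont = np.zeros(len(cur), dtype=bool)
            if ok.any():
                ni = tuple(nxt[ok].T)
                cont[ok] = msk[ni] & (lev[ni] == run_level[ok])
            ended = ~cont
            np.add.at(counts, (run_level[ended] - 1, length[ended] - 1), 1.0)
            cur, run_level, length = nxt[cont], run_level[cont], length[cont] + 1
    return RunLengthMatrix(counts=counts)


def hgre(m: RunLengthMatrix) -> float:
    """High grey-level run emphasis: (1/Nr) * sum r(i,l) * i^2."""
    nr = m.n_runs
    if nr == 0:
        raise ValueError("run-length matrix is empty")
    i = np.arange(1, m.counts.shape[0] + 1, dtype=np.float64)
    return float((m.counts.sum(axis=1) * i**2).sum() / nr)


_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def build_glszm(q: QuantizedVolume) -> SizeZoneMatrix:
    """Size-zone matrix: 26-connected constant-level zones within the mask."""
    if q.n_masked == 0:
        raise ValueError("empty lesion mask")
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for level in np.unique(q.levels[q.mask]):
        labels, n = ndimage.label(q.levels == level, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        zone_sizes[int(level)] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((q.n_levels, max_size), dtype=np.float64)
    for level, sizes in zone_sizes.items():
        for s in sizes:
            counts[level - 1, s - 1] += 1.0
    return SizeZoneMatrix(counts=counts)


def zlnu(m: SizeZoneMatrix) -> float:
    """Zone (size) non-uniformity: (1/Nz) * sum_s (sum_i z(i,s))^2."""
    nz = m.n_zones
    if nz == 0:
        raise ValueError("size-zone matrix is empty")
    per_size = m.counts.sum(axis=0)
    return float((per_size**2).sum() / nz)


def szhge(m: SizeZoneMatrix) -> float:
    """Short-zone high grey-level emphasis: (1/Nz) * sum z(i,s) * i^2 / s^2."""
    nz = m.n_zones
    if nz == 0:
        raise ValueError("size-zone matrix is empty")
    g, smax = m.counts.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    s = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    return float((m.counts * i**2 / s**2).sum() / nz)


def texture_features(
    vol: SuvVolume, mask: LesionMask, n_levels: int = 64
) -> dict[str, float]:
    """All six heterogeneity features as a named map."""
    q = quantize(vol, mask, n_levels)
    hom, ent, dis = glcm_features(build_glcm(q))
    return {
        "homogeneity": hom,
        "entropy": ent,
        "dissimilarity": dis,
        "hgre": hgre(build_glrlm(q)),
        "zlnu": zlnu(build_glszm(q)),
        "szhge": szhge(build_glszm(q)),
    }
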