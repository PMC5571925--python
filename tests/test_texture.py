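"""Quantization and the three texture matrices, checked against brute-force
pair-enumeration / run-scan / flood-fill oracles."""

import numpy as np
import pytest

import petsarc as ps
from petsarc.texture import DIRECTIONS_13
from conftest import quantized_from_arrays, random_quantized
from oracles import glcm_bruteforce, glrlm_bruteforce, glszm_bruteforce


def _uniform_q(shape=(3, 3, 3), level=1, n_levels=4):
    levels = np.full(shape, level, dtype=np.int32)
    return quantized_from_arrays(levels, np.ones(shape, bool), n_levels)


def test_direction_set_is_half_of_26_neighbourhood():
    assert len(DIRECTIONS_13) == 13
    s = set(DIRECTIONS_13)
    assert all(tuple(-x for x in d) not in s for d in s)


def test_quantize_hand_example():
    vals = np.array([0.0, 0.5, 1.0]).reshape(1, 1, 3)
    vol = ps.SuvVolume(vals, (1, 1, 1))
    mask = ps.LesionMask(np.ones((1, 1, 3), bool), (1, 1, 1))
    q = ps.quantize(vol, mask, n_levels=2)
    assert q.levels[0, 0].tolist() == [1, 2, 2]


def test_quantize_constant_region_all_level_one():
    vol = ps.SuvVolume(np.full((2, 2, 2), 4.2), (1, 1, 1))
    mask = ps.LesionMask(np.ones((2, 2, 2), bool), (1, 1, 1))
    q = ps.quantize(vol, mask, n_levels=64)
    assert (q.levels == 1).all()


def test_quantize_affine_invariance():
    rng = np.random.default_rng(3)
    for _ in range(20):
        vals = rng.gamma(2, 1, (5, 5, 5))
        mask = rng.random(vals.shape) < 0.7
        mask[0, 0, 0] = True
        vol = ps.SuvVolume(vals, (1, 1, 1))
        a, b = rng.uniform(0.1, 5), rng.uniform(0, 3)
        vol2 = ps.SuvVolume(a * vals + b, (1, 1, 1))
        m = ps.LesionMask(mask, (1, 1, 1))
        assert np.array_equal(
            ps.quantize(vol, m, 16).levels, ps.quantize(vol2, m, 16).levels
        )


def test_glcm_uniform_region():
    m = ps.build_glcm(_uniform_q())
    assert m.probabilities[0, 0] == 1.0
    assert m.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_glcm_single_pair_symmetrized():
    levels = np.array([[[1, 2]]], dtype=np.int32)
    q = quantized_from_arrays(levels, np.ones((1, 1, 2), bool), 2)
    m = ps.build_glcm(q)
    assert m.probabilities[0, 1] == m.probabilities[1, 0] == 0.5


def test_glcm_matches_bruteforce_on_random_volumes():
    rng = np.random.default_rng(11)
    for _ in range(25):
        levels, mask = random_quantized(rng)
        q = quantized_from_arrays(levels, mask, 4)
        try:
            m = ps.build_glcm(q)
        except ValueError:
            assert glcm_bruteforce(levels, mask, 4).sum() == 0
            continue
        np.testing.assert_allclose(
            m.probabilities, glcm_bruteforce(levels, mask, 4), atol=1e-13
        )


def test_glcm_no_pairs_rejected():
    levels = np.ones((1, 1, 1), dtype=np.int32)
    q = quantized_from_arrays(levels, np.ones((1, 1, 1), bool), 2)
    with pytest.raises(ValueError, match="no voxel pairs"):
        ps.build_glcm(q)


def test_glcm_features_single_cell():
    hom, ent, dis = ps.glcm_features(ps.build_glcm(_uniform_q()))
    assert (hom, ent, dis) == (1.0, 0.0, 0.0)


def test_glcm_features_two_cell_hand_arithmetic():
    levels = np.array([[[1, 2]]], dtype=np.int32)
    q = quantized_from_arrays(levels, np.ones((1, 1, 2), bool), 2)
    hom, ent, dis = ps.glcm_features(ps.build_glcm(q))
    assert hom == pytest.approx(0.5)
    assert ent == pytest.approx(1.0)
    assert dis == pytest.approx(1.0)


def test_glcm_entropy_bounded():
    rng = np.random.default_rng(5)
    for _ in range(10):
        levels, mask = random_quantized(rng, shape=(5, 5, 5), n_levels=4)
        q = quantized_from_arrays(levels, mask, 4)
        try:
            _, ent, _ = ps.glcm_features(ps.build_glcm(q))
        except ValueError:
            continue
        assert 0 <= ent <= 2 * np.log2(4)


def test_glrlm_single_axis_run():
    levels = np.ones((1, 1, 4), dtype=np.int32)
    q = quantized_from_arrays(levels, np.ones((1, 1, 4), bool), 4)
    m = ps.build_glrlm(q)
    assert m.counts[0, 3] == 1  # one run of length 4 along the long axis
    assert ps.hgre(m) == 1.0


def test_hgre_top_level_is_g_squared():
    q = _uniform_q(shape=(3, 3, 3), level=64, n_levels=64)
    assert ps.hgre(ps.build_glrlm(q)) == 64.0**2


def test_glrlm_matches_bruteforce_on_random_volumes():
    rng = np.random.default_rng(17)
    for _ in range(25):
        levels, mask = random_quantized(rng)
        q = quantized_from_arrays(levels, mask, 4)
        np.testing.assert_array_equal(
            ps.build_glrlm(q).counts[:, : max(levels.shape)],
            glrlm_bruteforce(levels, mask, 4),
        )


def test_glszm_uniform_single_zone():
    q = _uniform_q(shape=(2, 3, 2), level=2, n_levels=4)
    m = ps.build_glszm(q)
    assert m.n_zones == 1
    assert ps.zlnu(m) == 1.0
    assert ps.szhge(m) == pytest.approx(2**2 / 12.0**2)


def test_glszm_two_level_checkerboard_matches_flood_fill():
    """Under 26-connectivity a strict 2-level checkerboard forms exactly two
    zones (equal-parity voxels touch diagonally); the flood-fill oracle is the
    ground truth."""
    idx = np.indices((4, 4, 4))
    levels = ((idx.sum(axis=0) % 2) + 1).astype(np.int32)
    mask = np.ones((4, 4, 4), bool)
    q = quantized_from_arrays(levels, mask, 2)
    got = ps.build_glszm(q)
    exp = glszm_bruteforce(levels, mask, 2)
    np.testing.assert_array_equal(got.counts[:, : exp.shape[1]], exp)
    assert got.n_zones == 2


def test_glszm_all_singleton_zones():
    """Eight-level parity coding makes every voxel differ from all 26
    neighbours, so every voxel is its own zone and ZLNU = Nz."""
    idx = np.indices((4, 4, 4))
    levels = (1 + (idx[0] % 2) + 2 * (idx[1] % 2) + 4 * (idx[2] % 2)).astype(np.int32)
    q = quantized_from_arrays(levels, np.ones((4, 4, 4), bool), 8)
    m = ps.build_glszm(q)
    assert m.n_zones == 64
    assert m.counts[:, 0].sum() == 64
    assert ps.zlnu(m) == 64.0


def test_glszm_matches_bruteforce_on_random_volumes():
    rng = np.random.default_rng(23)
    for _ in range(25):
        levels, mask = random_quantized(rng)
        q = quantized_from_arrays(levels, mask, 4)
        got = ps.build_glszm(q).counts
        exp = glszm_bruteforce(levels, mask, 4)
        np.testing.assert_array_equal(got[:, : exp.shape[1]], exp)
        assert got[:, exp.shape[1] :].sum() == 0


def test_glszm_mass_conservation():
    rng = np.random.default_rng(29)
    for _ in range(20):
        levels, mask = random_quantized(rng, shape=(6, 6, 6))
        q = quantized_from_arrays(levels, mask, 4)
        counts = ps.build_glszm(q).counts
        sizes = np.arange(1, counts.shape[1] + 1)
        assert (counts * sizes).sum() == mask.sum()


def test_exhaustive_two_level_planes_match_oracles():
    """Every 2-level pattern on a full 3x3x1 mask, GLCM and GLSZM exactly."""
    mask = np.ones((3, 3, 1), bool)
    for code in range(2**9):
        levels = (np.array([(code >> k) & 1 for k in range(9)]) + 1).reshape(3, 3, 1)
        q = quantized_from_arrays(levels.astype(np.int32), mask, 2)
        np.testing.assert_allclose(
            ps.build_glcm(q).probabilities, glcm_bruteforce(levels, mask, 2), atol=1e-13
        )
        got = ps.build_glszm(q).counts
        exp = glszm_bruteforce(levels, mask, 2)
        np.testing.assert_array_equal(got[:, : exp.shape[1]], exp)


def test_features_invariant_to_axis_permutation():
    rng = np.random.default_rng(31)
    vals = rng.gamma(2, 1, (6, 7, 8))
    mask = rng.random(vals.shape) < 0.7
    vol = ps.SuvVolume(vals, (1, 1, 1))
    m = ps.LesionMask(mask, (1, 1, 1))
    ref = ps.texture_features(vol, m, n_levels=8)
    for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
        volp = ps.SuvVolume(vals.transpose(perm), (1, 1, 1))
        mp = ps.LesionMask(mask.transpose(perm), (1, 1, 1))
        got = ps.texture_features(volp, mp, n_levels=8)
        for k in ref:
            assert got[k] == pytest.approx(ref[k], rel=1e-12), k


def test_features_invariant_to_affine_intensity_transform():
    rng = np.random.default_rng(37)
    vals = rng.gamma(2, 1, (6, 6, 6))
    mask = rng.random(vals.shape) < 0.8
    m = ps.LesionMask(mask, (1, 1, 1))
    ref = ps.texture_features(ps.SuvVolume(vals, (1, 1, 1)), m, n_levels=8)
    got = ps.texture_features(ps.SuvVolume(2.5 * vals + 1.0, (1, 1, 1)), m, n_levels=8)
    for k in ref:
        assert got[k] == pytest.approx(ref[k], rel=1e-12), k
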