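"""SUV intensity/volume metrics and percent-change deltas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petsarc as ps
from petsarc.intensity import PEAK_SPHERE_RADIUS_MM
from oracles import suv_peak_bruteforce


def _vol_mask(values, spacing=(2.0, 2.0, 2.0), mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return ps.SuvVolume(values, spacing), ps.LesionMask(mask, spacing)


def test_suv_basic_constant_region():
    vol, mask = _vol_mask(np.full((3, 3, 3), 3.0))
    assert ps.suv_basic(vol, mask) == (3.0, 3.0)


def test_suv_basic_hand_values():
    vals = np.zeros((1, 1, 4))
    vals[0, 0] = [1, 2, 3, 4]
    vol, mask = _vol_mask(vals)
    assert ps.suv_basic(vol, mask) == (4.0, 2.5)


def test_suv_basic_empty_mask_rejected():
    vol, _ = _vol_mask(np.ones((3, 3, 3)))
    with pytest.raises(ValueError, match="empty"):
        ps.suv_basic(vol, ps.LesionMask(np.zeros((3, 3, 3), bool), vol.spacing))


def test_suvmax_of_inserted_peak_recovered_exactly():
    spec = ps.PhantomSpec(
        grid_shape=(25, 25, 25), spacing=(2, 2, 2), semi_axes=(12, 12, 12),
        lesion_suv=12.7, background_suv=1.0, noise_sd=0.0, background_noise_sd=0.0,
    )
    vol, mask = ps.generate_phantom(spec)
    smax, _ = ps.suv_basic(vol, mask)
    assert smax == 12.7


def test_suv_peak_uniform_large_lesion():
    """A uniform lesion much larger than the 1-cm^3 sphere peaks at its SUV."""
    vals = np.ones((21, 21, 21))
    vals[4:17, 4:17, 4:17] = 5.0
    mask = np.zeros(vals.shape, bool)
    mask[4:17, 4:17, 4:17] = True
    vol, m = _vol_mask(vals, spacing=(2, 2, 2), mask=mask)
    assert ps.suv_peak(vol, m) == pytest.approx(5.0, abs=1e-12)


def test_suv_peak_single_hot_voxel_matches_enumeration():
    """Spacing 4 mm: the 6.204 mm sphere holds the center, its 6 face
    neighbours (4 mm) and 12 edge-diagonal neighbours (4*sqrt(2) mm) = 19
    voxel centers."""
    vals = np.ones((9, 9, 9))
    vals[4, 4, 4] = 10.0
    mask = np.zeros(vals.shape, bool)
    mask[4, 4, 4] = True
    vol, m = _vol_mask(vals, spacing=(4, 4, 4), mask=mask)
    got = ps.suv_peak(vol, m)
    expected = suv_peak_bruteforce(vals, mask, (4, 4, 4), PEAK_SPHERE_RADIUS_MM)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx((10.0 + 18 * 1.0) / 19.0)


def test_suv_peak_too_coarse_spacing_names_spacing():
    vol, m = _vol_mask(np.ones((3, 3, 3)), spacing=(8, 8, 8))
    with pytest.raises(ValueError, match="8"):
        ps.suv_peak(vol, m)


def test_suv_peak_le_suvmax_property():
    """Sphere averaging never exceeds the max voxel across random phantoms."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        vals = rng.gamma(2.0, 1.5, (10, 10, 10))
        mask = rng.random(vals.shape) < 0.5
        if not mask.any():
            continue
        vol, m = _vol_mask(vals, spacing=(3, 3, 3), mask=mask)
        smax, _ = ps.suv_basic(vol, m)
        assert ps.suv_peak(vol, m) <= smax + 1e-12


def test_suv_peak_tie_invariance():
    vals = np.ones((7, 7, 7))
    vals[2, 2, 2] = vals[4, 4, 4] = 9.0
    mask = np.ones(vals.shape, bool)
    vol, m = _vol_mask(vals, spacing=(3, 3, 3), mask=mask)
    flipped, _ = _vol_mask(vals[::-1, ::-1, ::-1].copy(), spacing=(3, 3, 3))
    assert ps.suv_peak(vol, m) == pytest.approx(ps.suv_peak(flipped, m), rel=1e-12)


def test_mtv_exact_and_tlg_identity():
    vals = np.full((5, 5, 5), 3.0)
    mask = np.zeros(vals.shape, bool)
    mask.ravel()[:100] = True
    vol, m = _vol_mask(vals, spacing=(2, 2, 2), mask=mask)
    mtv, tlg = ps.mtv_tlg(vol, m)
    assert mtv == 0.8  # 100 voxels * 8 mm^3 / 1000
    assert tlg == pytest.approx(2.4, rel=1e-12)
    _, smean = ps.suv_basic(vol, m)
    assert tlg == pytest.approx(smean * mtv, rel=1e-9)


def test_mtv_scales_with_voxel_volume():
    mask = np.ones((4, 4, 4), bool)
    for spacing in ((1, 1, 1), (2, 2, 2), (1, 2, 3)):
        vol, m = _vol_mask(np.ones((4, 4, 4)), spacing=spacing, mask=mask)
        mtv, _ = ps.mtv_tlg(vol, m)
        assert mtv == pytest.approx(64 * np.prod(spacing) / 1000.0, rel=1e-12)


def test_mtv_empty_mask_policy():
    vol, _ = _vol_mask(np.ones((3, 3, 3)))
    empty = ps.LesionMask(np.zeros((3, 3, 3), bool), vol.spacing)
    with pytest.raises(ValueError):
        ps.mtv_tlg(vol, empty)
    assert ps.mtv_tlg(vol, empty, allow_empty=True) == (0.0, 0.0)


def test_delta_percent_hand_values():
    d = ps.delta_percent({"suv_max": 10.0}, {"suv_max": 4.0}, features=("suv_max",))
    assert d["suv_max"] == pytest.approx(-60.0)


def test_delta_percent_complete_disappearance_is_minus_100():
    d = ps.delta_percent({"tlg": 52.7}, {"tlg": 0.0}, features=("tlg",))
    assert d["tlg"] == -100.0


def test_delta_percent_identity():
    f = {"suv_max": 3.3, "mtv": 12.0}
    d = ps.delta_percent(f, dict(f), features=("suv_max", "mtv"))
    assert all(v == 0.0 for v in d.values())


def test_delta_percent_zero_baseline_missing_with_warning():
    with pytest.warns(UserWarning, match="undefined"):
        d = ps.delta_percent({"mtv": 0.0}, {"mtv": 1.0}, features=("mtv",))
    assert np.isnan(d["mtv"])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(pre=st.floats(0.01, 1e4), s=st.floats(0.0, 10.0))
def test_delta_percent_scaling_law(pre, s):
    """post = s * pre gives exactly 100(s - 1) for any positive baseline."""
    d = ps.delta_percent({"tlg": pre}, {"tlg": pre * s}, features=("tlg",))
    assert d["tlg"] == pytest.approx(100.0 * (s - 1.0), rel=1e-9, abs=1e-9)


def test_uniform_scaling_gives_100_s_minus_1():
    """post = s * pre on the same mask: every intensity delta is 100(s-1)."""
    rng = np.random.default_rng(1)
    vals = rng.gamma(3.0, 1.0, (8, 8, 8)) + 0.5
    mask = rng.random(vals.shape) < 0.6
    vol0, m = _vol_mask(vals, mask=mask)
    s = 0.37
    vol1 = ps.SuvVolume(vals * s, vol0.spacing, "post_cht")
    for f, pre, post in (
        ("suv_max", ps.suv_basic(vol0, m)[0], ps.suv_basic(vol1, m)[0]),
        ("suv_mean", ps.suv_basic(vol0, m)[1], ps.suv_basic(vol1, m)[1]),
        ("suv_peak", ps.suv_peak(vol0, m), ps.suv_peak(vol1, m)),
    ):
        d = ps.delta_percent({f: pre}, {f: post}, features=(f,))
        assert d[f] == pytest.approx(100 * (s - 1), rel=1e-9)
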