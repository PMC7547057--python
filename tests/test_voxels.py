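"""Voxel-wise analysis: QSD, differences, exceedance, masks, localization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petac
from petac.errors import GridMismatchError, PetacError
from petac.roi import ROISpec
from petac.volume import ImageVolume
from petac.voxels import (QSD, compute_qsd, exceedance_summary,
                          paired_voxel_test, significance_mask,
                          spatial_localization_score, voxel_difference)


def _suv(values, spacing=(2.0, 2.0, 2.0)):
    return ImageVolume(np.asarray(values, dtype=float), spacing, "SUV")


# ----------------------------------------------------------------------
def test_qsd_equals_enumeration_sd():
    rng = np.random.default_rng(5)
    vol = _suv(rng.random((12, 12, 3)) + 2.0)
    roi = ROISpec("liver", 1, (5.5, 6.0), 5.0)
    qsd = compute_qsd(vol, roi)
    vals = [vol.values[i, j, 1]
            for i in range(12) for j in range(12)
            if ((i - 5.5) * 2) ** 2 + ((j - 6.0) * 2) ** 2 <= 25.0 + 1e-9]
    assert qsd.value == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
    assert qsd.source_roi == "liver"


def test_constant_reference_gives_invalid_qsd():
    vol = _suv(np.full((12, 12, 3), 2.5))
    with pytest.raises(PetacError, match="QSD"):
        compute_qsd(vol, ROISpec("liver", 1, (5.5, 6.0), 5.0))


# ----------------------------------------------------------------------
def test_voxel_difference_sign_and_antisymmetry():
    rr = _suv([[[2.0]]])
    tr = _suv([[[1.9]]])
    d = voxel_difference(tr, rr)
    assert d.values.flat[0] == pytest.approx(0.1)  # underestimation positive
    assert np.array_equal(voxel_difference(tr, rr).values,
                          -voxel_difference(rr, tr).values)


def test_voxel_difference_never_resamples():
    rr = _suv(np.zeros((4, 4, 4)))
    tr = _suv(np.zeros((4, 4, 2)))
    with pytest.raises(GridMismatchError):
        voxel_difference(tr, rr)


# ----------------------------------------------------------------------
def test_self_comparison_is_degenerate():
    rng = np.random.default_rng(0)
    rr = _suv(rng.random((8, 8, 4)))
    assert math.isnan(paired_voxel_test(rr, rr))


def test_systematic_offset_is_detected():
    rng = np.random.default_rng(1)
    base = rng.random((10, 10, 10)) + 1.0
    rr = _suv(base)
    tr = _suv(base - 0.01 + rng.normal(0, 1e-4, base.shape))
    assert paired_voxel_test(tr, rr) < 1e-4


def test_two_sidedness_is_symmetric():
    rng = np.random.default_rng(2)
    rr = _suv(rng.random((6, 6, 6)) + 1)
    tr = _suv(rng.random((6, 6, 6)) + 1)
    assert paired_voxel_test(tr, rr) == pytest.approx(paired_voxel_test(rr, tr))


# ----------------------------------------------------------------------
def test_toy_exceedance_count():
    """10 voxels, QSD 0.1, exactly 3 differing by 0.2 -> 30% exceedance."""
    rr = _suv(np.full((10, 1, 1), 2.0))
    tr_vals = np.full((10, 1, 1), 2.0)
    tr_vals[:3, 0, 0] = 1.8
    tr = _suv(tr_vals)
    diff = voxel_difference(tr, rr)
    summ = exceedance_summary(diff, QSD(0.1, "liver"), rr)
    assert summ["percent_gt_qsd"] == pytest.approx(30.0)
    mask = significance_mask(diff, QSD(0.1, "liver"))
    assert mask.values.sum() == 3
    assert np.array_equal(np.flatnonzero(mask.values), [0, 1, 2])


def test_difference_equal_to_qsd_does_not_exceed():
    # 0.125 is exactly representable, so |diff| == QSD holds bit-exactly
    rr = _suv(np.full((5, 1, 1), 2.0))
    tr = _suv(np.full((5, 1, 1), 1.875))
    diff = voxel_difference(tr, rr)
    summ = exceedance_summary(diff, QSD(0.125, "liver"), rr)
    assert summ["percent_gt_qsd"] == 0.0
    assert significance_mask(diff, QSD(0.125, "liver")).values.sum() == 0


def test_zero_difference_summary():
    rr = _suv(np.full((4, 4, 4), 1.5))
    diff = voxel_difference(rr, rr)
    summ = exceedance_summary(diff, QSD(0.1, "liver"), rr)
    assert summ["percent_gt_qsd"] == 0.0
    assert summ["max_diff_percent"] == 0.0
    assert summ["mean_diff_percent"] == 0.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 0.5))
def test_exceedance_matches_exhaustive_count(seed, qsd_value):
    """Exceedance percent, mask and relative stats equal a brute-force loop."""
    rng = np.random.default_rng(seed)
    shape = (rng.integers(2, 14), rng.integers(2, 14), rng.integers(1, 8))
    rr_vals = rng.random(shape) * 3.0
    tr_vals = np.clip(rr_vals + rng.normal(0, 0.3, shape), 0, None)
    rr, tr = _suv(rr_vals), _suv(tr_vals)
    diff = voxel_difference(tr, rr)
    qsd = QSD(qsd_value, "liver")
    summ = exceedance_summary(diff, qsd, rr)
    mask = significance_mask(diff, qsd)

    n_exceed = 0
    rel = []
    for idx in np.ndindex(shape):
        d = rr_vals[idx] - tr_vals[idx]
        if abs(d) > qsd_value:
            n_exceed += 1
            assert mask.values[idx] == 1.0
        else:
            assert mask.values[idx] == 0.0
        if rr_vals[idx] > 0.1:
            rel.append(100.0 * d / rr_vals[idx])
    n_total = int(np.prod(shape))
    assert summ["percent_gt_qsd"] == pytest.approx(100.0 * n_exceed / n_total)
    assert int(mask.values.sum()) == n_exceed
    if rel:
        assert summ["max_diff_percent"] == pytest.approx(max(rel))
        assert summ["mean_diff_percent"] == pytest.approx(np.mean(rel))
        assert summ["mean_diff_percent"] <= summ["max_diff_percent"]


def test_empty_support_rejected():
    rr = _suv(np.ones((3, 3, 3)))
    diff = voxel_difference(rr, rr)
    with pytest.raises(PetacError, match="support"):
        exceedance_summary(diff, QSD(0.1, "liver"), rr,
                           support_mask=np.zeros((3, 3, 3), dtype=bool))


# ----------------------------------------------------------------------
def test_uniform_random_mask_has_flat_enrichment():
    rng = np.random.default_rng(3)
    shape = (40, 40, 10)
    mask_vals = (rng.random(shape) < 0.2).astype(float)
    mask = ImageVolume(mask_vals, (2, 2, 2), "MASK")
    regions = {"a": np.zeros(shape, dtype=bool), "b": np.zeros(shape, dtype=bool)}
    regions["a"][:20] = True
    regions["b"][20:] = True
    df = spatial_localization_score(mask, regions)
    assert np.allclose(df.enrichment, 1.0, atol=0.05)


def test_mask_confined_to_one_region():
    shape = (10, 10, 4)
    tumour = np.zeros(shape, dtype=bool)
    tumour[4:6, 4:6, 1:3] = True
    mask = ImageVolume(tumour.astype(float), (2, 2, 2), "MASK")
    regions = {"tumour": tumour, "background": ~tumour}
    df = spatial_localization_score(mask, regions).set_index("region")
    global_rate = tumour.mean()
    assert df.loc["tumour", "enrichment"] == pytest.approx(1.0 / global_rate)
    assert df.loc["background", "exceedance_rate"] == 0.0


def test_region_grid_mismatch_rejected():
    mask = ImageVolume(np.zeros((4, 4, 4)), (2, 2, 2), "MASK")
    with pytest.raises(PetacError, match="grid"):
        spatial_localization_score(mask, {"bad": np.zeros((4, 4, 2), dtype=bool)})
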