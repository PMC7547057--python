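"""ROI statistics: enumeration oracles, COV arithmetic, paired COV testing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petac
from petac.errors import ROIError
from petac.roi import (ROISpec, default_rois, paired_cov_test, roi_stats,
                       suv_cov, delta_cov)
from petac.volume import ImageVolume


def _volume(values):
    return ImageVolume(np.asarray(values, dtype=float), (2.0, 2.0, 2.0), "SUV")


def _enumerate_roi(volume, roi):
    """Brute-force oracle: walk every voxel of the slice, collect members."""
    vals = []
    nx, ny, _ = volume.shape
    sx, sy, _ = volume.spacing
    for i in range(nx):
        for j in range(ny):
            d2 = ((i - roi.center[0]) * sx) ** 2 + ((j - roi.center[1]) * sy) ** 2
            if d2 <= roi.radius_mm ** 2 + 1e-9:
                vals.append(volume.values[i, j, roi.slice_index])
    return np.array(vals)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_roi_stats_match_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    vol = _volume(rng.random((16, 16, 4)) + 0.5)
    roi = ROISpec("probe", 2, (7.5, 8.0), 6.0)
    st_ = roi_stats(vol, roi)
    vals = _enumerate_roi(vol, roi)
    assert st_.n_voxels == len(vals)
    assert st_.mean == pytest.approx(vals.mean(), abs=1e-12)
    assert st_.max == pytest.approx(vals.max(), abs=1e-12)
    assert st_.sd == pytest.approx(vals.std(ddof=1), abs=1e-12)
    assert st_.cov_percent == pytest.approx(vals.std(ddof=1) / vals.mean() * 100, abs=1e-12)


def test_constant_volume_has_zero_cov():
    vol = _volume(np.full((8, 8, 2), 2.5))
    st_ = roi_stats(vol, ROISpec("flat", 0, (3.5, 3.5), 4.0))
    assert st_.mean == 2.5 and st_.sd == 0.0 and st_.cov_percent == 0.0


def test_voxel_center_on_radius_counts_as_inside():
    vol = _volume(np.zeros((9, 9, 1)))
    # neighbors at exactly 2 mm from the center with radius 2 mm
    st_ = roi_stats(vol.with_values(np.ones((9, 9, 1))),
                    ROISpec("tie", 0, (4.0, 4.0), 2.0))
    assert st_.n_voxels == 5  # center + 4 edge-distance neighbors


def test_roi_validation_errors():
    vol = _volume(np.ones((8, 8, 2)))
    with pytest.raises(ROIError, match="outside"):
        roi_stats(vol, ROISpec("edge", 0, (0.0, 4.0), 6.0))
    with pytest.raises(ROIError, match="slice"):
        roi_stats(vol, ROISpec("deep", 5, (4.0, 4.0), 2.0))
    with pytest.raises(ROIError, match="mean"):
        roi_stats(_volume(np.zeros((8, 8, 2))), ROISpec("cold", 0, (3.5, 3.5), 4.0))


def test_suv_cov_values():
    assert suv_cov(0.1, 2.5) == pytest.approx(4.0)
    assert suv_cov(0.0, 1.7) == 0.0
    assert suv_cov(0.3, 2.5) == pytest.approx(12.0)
    with pytest.raises(ROIError):
        suv_cov(0.1, 0.0)


def test_delta_cov_sign_convention():
    # FBP noisier than IR -> positive difference
    assert delta_cov(6.2, 5.0) == pytest.approx(1.2)
    assert delta_cov(5.0, 5.0) == 0.0
    assert delta_cov(4.0, 5.5) < 0


def test_paired_cov_test_matches_closed_form_three_pairs():
    """Hand-computed paired t on pairs (1,2), (2,2), (3,5), to 1e-10.

    d = (-1, 0, -2): mean -1, sd 1, t = -sqrt(3); for 2 degrees of freedom
    the two-sided p has the closed form 1 - |t| / sqrt(2 + t^2).
    """
    res = paired_cov_test([1.0, 2.0, 3.0], [2.0, 2.0, 5.0])
    d = np.array([-1.0, 0.0, -2.0])
    t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(3))
    p_hand = 1.0 - abs(t_hand) / math.sqrt(2.0 + t_hand ** 2)
    assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
    assert res.p_value == pytest.approx(p_hand, abs=1e-10)
    assert (res.min, res.median, res.max) == (-2.0, -1.0, 0.0)
    assert res.mean == pytest.approx(-1.0)


def test_identical_pairs_are_degenerate_not_an_error():
    res = paired_cov_test([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
    assert res.degenerate
    assert math.isnan(res.p_value)
    assert res.min == res.mean == res.max == 0.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.1, 50), st.floats(0.1, 50)),
                min_size=2, max_size=24))
def test_delta_cov_summary_is_ordered(pairs):
    fbp, ir = zip(*pairs)
    res = paired_cov_test(list(fbp), list(ir))
    assert res.min <= res.median <= res.max
    ulp = 1e-9 * max(1.0, abs(res.max), abs(res.min))
    assert res.min - ulp <= res.mean <= res.max + ulp


def test_default_rois_sit_in_their_compartments(small_spec, small_bundle):
    rois = default_rois(small_spec)
    assert {r.name for r in rois} == {"liver", "soft_tissue",
                                      "beam_hardening_soft_tissue", "tumour"}
    tumour = next(r for r in rois if r.name == "tumour")
    assert tumour.statistic == "max"
    gt = small_bundle.ground_truth
    liver = next(r for r in rois if r.name == "liver")
    assert roi_stats(gt, liver).mean == pytest.approx(2.5)
    soft = next(r for r in rois if r.name == "soft_tissue")
    assert roi_stats(gt, soft).mean == pytest.approx(1.0)
    assert roi_stats(gt, tumour).max == pytest.approx(4.0)


def test_roi_yaml_round_trip(tmp_path, small_spec):
    rois = default_rois(small_spec)
    path = petac.save_rois(rois, tmp_path / "rois.yaml")
    assert petac.load_rois(path) == rois
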