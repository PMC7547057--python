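"""Report pipeline and real-volume analysis mode."""

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

import petac
from petac.reporting import RunConfig, analyze_external, run_study, table1
from petac.volume import ImageVolume


@pytest.fixture(scope="module")
def study_out(tmp_path_factory):
    cfg = RunConfig(shape=(64, 64, 16), spacing_mm=(8.0, 8.0, 10.0), seed=0)
    out = tmp_path_factory.mktemp("study")
    manifest = run_study(cfg, out)
    return cfg, out, manifest


def test_table1_covers_the_grid():
    t1 = table1(petac.default_protocols())
    assert len(t1) == 24
    assert t1.ctdi_mgy.min() == pytest.approx(0.3)
    assert t1.ctdi_mgy.max() == pytest.approx(3.3)


def test_run_study_writes_voxel_table_with_degenerate_reference_row(study_out):
    _, _, manifest = study_out
    t3 = pd.read_csv(manifest["files"]["table3"])
    assert len(t3) == 48
    ref_rows = t3[t3.is_reference]
    assert len(ref_rows) == 1
    assert math.isnan(ref_rows.percent_gt_qsd.iloc[0])
    assert math.isnan(ref_rows.p_value.iloc[0])
    non_ref = t3[~t3.is_reference]
    assert len(non_ref) == 47
    assert non_ref.percent_gt_qsd.between(0, 100).all()


def test_run_study_manifest_records_seed_and_checksums(study_out):
    cfg, out, manifest = study_out
    assert manifest["seed"] == cfg.seed
    stored = json.loads((Path(manifest["files"]["table3"]).parent / "manifest.json")
                        .read_text())
    assert stored["outputs"] == manifest["outputs"]
    assert stored["qsd_suv"] > 0


def test_reference_only_config_reports_zero_comparisons(tmp_path):
    cfg = RunConfig(shape=(64, 64, 16), spacing_mm=(8.0, 8.0, 10.0),
                    seed=3, restrict_to_reference=True, save_masks=False)
    m1 = run_study(cfg, tmp_path / "a")
    t3 = pd.read_csv(m1["files"]["table3"])
    assert len(t3) == 1 and t3.is_reference.all()
    # determinism: identical config -> identical checksums
    m2 = run_study(cfg, tmp_path / "b")
    assert m1["outputs"] == m2["outputs"]


def test_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(shape=(32, 32, 8), seed=9, support="all")
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    again = RunConfig.from_yaml(path)
    assert again == cfg
    with pytest.raises(petac.PetacError, match="unknown config field"):
        RunConfig.from_dict({"bogus": 1})


# ----------------------------------------------------------------------
def _write_nifti(path, values, spacing=(4.0, 4.0, 4.0)):
    vol = ImageVolume(np.asarray(values, dtype=float), spacing, "SUV")
    vol.to_nifti(path)
    return vol


def _toy_rois(path):
    rois = [petac.ROISpec("liver", 1, (5.0, 5.0), 9.0, "mean")]
    petac.save_rois(rois, path)
    return path


def test_analyze_external_matches_brute_force(tmp_path):
    rng = np.random.default_rng(0)
    rr_vals = rng.random((12, 12, 4)) + 2.0
    tr_vals = rr_vals.copy()
    tr_vals[:4] -= 0.5  # a known, localized offset
    _write_nifti(tmp_path / "rr.nii", rr_vals)
    _write_nifti(tmp_path / "tr.nii", tr_vals)
    rois = _toy_rois(tmp_path / "rois.yaml")
    analyze_external(tmp_path / "rr.nii", [tmp_path / "tr.nii"], rois, tmp_path / "out")
    vox = pd.read_csv(tmp_path / "out" / "voxel_analysis.csv")
    # brute-force expectation
    mask_vals = [v for i in range(12) for j in range(12)
                 if ((i - 5.0) * 4) ** 2 + ((j - 5.0) * 4) ** 2 <= 81.0 + 1e-9
                 for v in [rr_vals[i, j, 1]]]
    qsd = np.std(mask_vals, ddof=1)
    expected_pct = 100.0 * (np.abs(rr_vals - tr_vals) > qsd).mean()
    assert vox.percent_gt_qsd.iloc[0] == pytest.approx(expected_pct)
    assert vox.p_value.iloc[0] < 1e-6


def test_analyze_external_self_comparison_is_degenerate(tmp_path):
    rng = np.random.default_rng(1)
    vals = rng.random((12, 12, 4)) + 2.0
    _write_nifti(tmp_path / "rr.nii", vals)
    rois = _toy_rois(tmp_path / "rois.yaml")
    analyze_external(tmp_path / "rr.nii", [tmp_path / "rr.nii"], rois, tmp_path / "out")
    vox = pd.read_csv(tmp_path / "out" / "voxel_analysis.csv")
    assert vox.percent_gt_qsd.iloc[0] == 0.0
    assert math.isnan(vox.p_value.iloc[0])


def test_analyze_external_grid_mismatch_names_file(tmp_path):
    _write_nifti(tmp_path / "rr.nii", np.ones((12, 12, 4)) + 1)
    _write_nifti(tmp_path / "small.nii", np.ones((12, 12, 2)) + 1)
    rois = _toy_rois(tmp_path / "rois.yaml")
    with pytest.raises(petac.GridMismatchError, match="small.nii"):
        analyze_external(tmp_path / "rr.nii", [tmp_path / "small.nii"],
                         rois, tmp_path / "out")


def test_analyze_external_missing_file(tmp_path):
    _write_nifti(tmp_path / "rr.nii", np.ones((8, 8, 2)) * 2)
    rois = _toy_rois(tmp_path / "rois.yaml")
    with pytest.raises(FileNotFoundError, match="nope.nii"):
        analyze_external(tmp_path / "rr.nii", [tmp_path / "nope.nii"],
                         rois, tmp_path / "out")


def test_cli_analyze_and_errors(tmp_path):
    from click.testing import CliRunner
    from petac.cli import main

    rng = np.random.default_rng(2)
    vals = rng.random((12, 12, 4)) + 2.0
    _write_nifti(tmp_path / "rr.nii", vals)
    _write_nifti(tmp_path / "tr.nii", vals * 0.95)
    rois = _toy_rois(tmp_path / "rois.yaml")
    runner = CliRunner()
    ok = runner.invoke(main, ["analyze", "--rr", str(tmp_path / "rr.nii"),
                              "--tr", str(tmp_path / "tr.nii"),
                              "--rois", str(rois),
                              "--out", str(tmp_path / "out")])
    assert ok.exit_code == 0, ok.output
    assert (tmp_path / "out" / "voxel_analysis.csv").exists()

    missing = runner.invoke(main, ["analyze", "--rr", str(tmp_path / "gone.nii"),
                                   "--tr", str(tmp_path / "tr.nii"),
                                   "--rois", str(rois),
                                   "--out", str(tmp_path / "out2")])
    assert missing.exit_code != 0
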