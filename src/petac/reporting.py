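"""Run orchestration: generate -> analyze -> report, plus real-volume mode.

``run_study`` drives the whole pipeline from a single ``RunConfig`` and
writes the study tables (acquisition grid + CTDI, the dCOV summary, the
voxel-comparison table), per-statistic-vs-CTDI plot data and figures,
significance masks as NIfTI, and a JSON manifest with version, seed and
checksums. Outputs are deterministic for a fixed config, so reruns are
byte-identical on the CSV side.

``analyze_external`` applies the same ROI and voxel analyses to
user-supplied co-registered NIfTI volumes without any simulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .ct import CTSimParams, DEFAULT_CT_PARAMS
from .errors import GridMismatchError, PetacError
from .phantom import analysis_regions, default_phantom
from .protocols import CTProtocol, REFERENCE_PROTOCOL, ctdi_model, default_protocols
from .roi import ROISpec, default_rois, delta_cov_table, load_rois, roi_table, save_rois
from .study import StudyBundle, generate_study
from .volume import ImageVolume
from .voxels import (compare_bundle, compute_qsd, significance_mask,
                     spatial_localization_score, voxel_difference)

log = logging.getLogger("petac")


@dataclass
class RunConfig:
    """Configuration of one simulated study run."""

    shape: tuple[int, int, int] = (128, 128, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    seed: int = 0
    counts_target: float = 2.0e5
    iterations: int = 3
    subsets: int = 3
    qsd_roi: str = "liver"
    support: str = "body"  # 'body' or 'all'
    relative_floor_suv: float = 0.1
    roi_file: str | None = None
    restrict_to_reference: bool = False
    save_volumes: bool = False
    save_masks: bool = True
    ct_params: CTSimParams = field(default_factory=CTSimParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PetacError(f"unknown config field(s): {sorted(bad)}")
        kwargs = dict(raw)
        if "ct_params" in kwargs and isinstance(kwargs["ct_params"], dict):
            kwargs["ct_params"] = CTSimParams(**kwargs["ct_params"])
        for key in ("shape", "spacing_mm"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["spacing_mm"] = list(self.spacing_mm)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:8]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def table1(protocols: list[CTProtocol]) -> pd.DataFrame:
    """The acquisition grid with its CTDI per parameter set."""
    acqs = sorted({p.acquisition for p in protocols})
    rows = [dict(mas=m, kvp=k, pitch=pi,
                 ctdi_mgy=round(ctdi_model(CTProtocol(m, k, pi)), 1))
            for (m, k, pi) in acqs]
    return pd.DataFrame(rows)


def _plot_vs_ctdi(df: pd.DataFrame, ycol: str, ylabel: str, path: Path,
                  ref_value: float | None = None, band: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for alg, marker in (("FBP", "o"), ("IR", "s")):
        sub = df[(df.algorithm == alg) & ~df[ycol].isna()]
        ax.scatter(sub.ctdi_mgy, sub[ycol], marker=marker, label=alg, alpha=0.7)
    if ref_value is not None:
        ax.axhline(ref_value, color="k", ls="--", lw=1)
        if band is not None:
            ax.axhline(ref_value - band, color="k", ls="-.", lw=1)
    ax.set_xlabel("CTDI (mGy)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def _overlay_figure(entry_vol: ImageVolume, mask: ImageVolume, path: Path,
                    title: str) -> None:
    """Orthogonal slices of a TR with its exceedance mask overlaid in red."""
    v = entry_vol.values
    m = mask.values > 0.5
    centers = [s // 2 for s in v.shape]
    slices = [(v[centers[0], :, :].T, m[centers[0], :, :].T),
              (v[:, centers[1], :].T, m[:, centers[1], :].T),
              (v[:, :, centers[2]].T, m[:, :, centers[2]].T)]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, (img, mm) in zip(axes, slices):
        ax.imshow(img, cmap="gray", vmin=0, vmax=4.5, origin="lower")
        overlay = np.zeros(img.shape + (4,))
        overlay[mm] = (1.0, 0.0, 0.0, 0.9)
        ax.imshow(overlay, origin="lower")
        ax.axis("off")
    fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def run_study(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full simulated study; returns the manifest dictionary."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s %(asctime)s %(message)s")
    out = Path(out_dir) / f"run-{config.digest()}"
    out.mkdir(parents=True, exist_ok=True)
    log.info("run directory %s (seed=%d)", out, config.seed)

    spec = default_phantom(shape=config.shape, spacing_mm=config.spacing_mm)
    protocols = [REFERENCE_PROTOCOL] if config.restrict_to_reference else default_protocols()
    log.info("generating study: %d reconstructions", len(protocols))
    bundle = generate_study(
        spec=spec, protocols=protocols, seed=config.seed,
        counts_target=config.counts_target, ct_params=config.ct_params,
        iterations=config.iterations, subsets=config.subsets,
    )
    rois = load_rois(config.roi_file) if config.roi_file else default_rois(spec)

    files: dict[str, str] = {}

    t1 = table1(protocols)
    files["table1"] = str(_write_csv(t1, out / "table1_acquisitions.csv"))

    rt = roi_table(bundle, rois)
    files["roi_stats"] = str(_write_csv(rt, out / "roi_stats.csv"))
    if not config.restrict_to_reference:
        t2 = delta_cov_table(bundle, rois)
        files["table2"] = str(_write_csv(t2, out / "table2_delta_cov.csv"))

    liver = next(r for r in rois if r.name == config.qsd_roi)
    qsd = compute_qsd(bundle.reference.volume, liver)
    t3, masks = compare_bundle(bundle, qsd, support=config.support,
                               relative_floor_suv=config.relative_floor_suv)
    files["table3"] = str(_write_csv(t3, out / "table3_voxel_analysis.csv"))
    log.info("QSD = %.4f SUV; %d comparison rows", qsd.value, len(t3))

    # Figure-shaped data: ROI statistic vs CTDI, COV vs CTDI, exceedance vs CTDI
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    rr_rows = rt[rt.is_reference]
    for roi in rois:
        sub = rt[rt.roi == roi.name]
        ref_val = float(rr_rows[rr_rows.roi == roi.name].statistic_of_record.iloc[0])
        band = qsd.value if roi.statistic == "mean" else None
        _plot_vs_ctdi(sub, "statistic_of_record",
                      f"{roi.name} SUV ({roi.statistic})",
                      fig_dir / f"fig2_{roi.name}.png", ref_val, band)
        _plot_vs_ctdi(sub, "cov_percent", f"{roi.name} SUV COV (%)",
                      fig_dir / f"fig3_{roi.name}.png")
    _plot_vs_ctdi(t3, "percent_gt_qsd", "% voxels > QSD", fig_dir / "fig5_exceedance.png")
    files["fig2_data"] = str(_write_csv(
        rt[["roi", "mas", "kvp", "pitch", "algorithm", "ctdi_mgy",
            "statistic_of_record", "cov_percent"]],
        out / "fig2_fig3_data.csv"))
    files["fig5_data"] = str(_write_csv(
        t3[["mas", "kvp", "pitch", "algorithm", "ctdi_mgy", "percent_gt_qsd"]],
        out / "fig5_data.csv"))

    # Fig 4-style scatter data + Fig 6-style overlays for extreme doses
    ctdis = sorted({round(e.ctdi_mgy, 1) for e in bundle.tests})
    picks = [e for e in bundle.tests
             if round(e.ctdi_mgy, 1) in (ctdis[0], ctdis[-1])] if ctdis else []
    body = bundle.body_mask()
    scatter_rows = []
    for e in picks:
        diff = voxel_difference(e.volume, bundle.reference.volume)
        rv = bundle.reference.volume.values[body]
        dv = diff.values[body]
        keep = slice(None, None, max(1, rv.size // 4000))
        scatter_rows.append(pd.DataFrame(dict(
            protocol=str(e.protocol), rr_suv=rv[keep], diff_suv=dv[keep])))
        fig6_name = "fig6_" + str(e.protocol).replace("/", "_").replace(".", "p") + ".png"
        _overlay_figure(e.volume, masks[str(e.protocol)], fig_dir / fig6_name,
                        str(e.protocol))
    if scatter_rows:
        files["fig4_data"] = str(_write_csv(pd.concat(scatter_rows, ignore_index=True),
                                            out / "fig4_scatter_data.csv"))

    if config.save_masks:
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for key, mvol in masks.items():
            name = key.replace("/", "_").replace(".", "p") + "_mask.nii"
            mvol.to_nifti(mask_dir / name, sidecar={"qsd_suv": qsd.value})
    if config.save_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for e in bundle.entries:
            name = str(e.protocol).replace("/", "_").replace(".", "p") + ".nii"
            e.volume.to_nifti(vol_dir / name, sidecar={
                "protocol": str(e.protocol), "ctdi_mgy": e.ctdi_mgy,
                "is_reference": e.is_reference})
        bundle.ground_truth.to_nifti(vol_dir / "ground_truth.nii")

    manifest = dict(
        software="petac", version=__version__, seed=config.seed,
        config=config.to_dict(), qsd_suv=qsd.value,
        n_reconstructions=len(bundle.entries),
        outputs={k: _sha256(Path(v)) for k, v in files.items()},
        files=files,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %d tables/figures to %s", len(files), out)
    return manifest


# ----------------------------------------------------------------------
def analyze_external(rr_path: str | Path, tr_paths: list[str | Path],
                     roi_file: str | Path, out_dir: str | Path,
                     qsd_roi: str = "liver",
                     relative_floor_suv: float = 0.1) -> dict:
    """ROI + voxel analysis of user-supplied co-registered NIfTI volumes.

    All volumes must share one grid; the first mismatching file is named in
    the error. No simulation is involved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rr_path = Path(rr_path)
    if not rr_path.exists():
        raise FileNotFoundError(f"reference volume not found: {rr_path}")
    rr = ImageVolume.from_nifti(rr_path, unit="SUV")
    trs = []
    for p in tr_paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"test volume not found: {p}")
        tr = ImageVolume.from_nifti(p, unit="SUV")
        if not rr.same_grid(tr):
            raise GridMismatchError(
                f"volume {p} grid {tr.shape}@{tr.spacing} does not match "
                f"reference {rr.shape}@{rr.spacing}")
        trs.append((p, tr))
    rois = load_rois(roi_file)
    liver = next(r for r in rois if r.name == qsd_roi)
    qsd = compute_qsd(rr, liver)

    roi_rows = []
    for name, vol in [("reference", rr)] + [(p.name, v) for p, v in trs]:
        for roi in rois:
            from .roi import roi_stats as _rs
            st = _rs(vol, roi)
            roi_rows.append(dict(volume=name, roi=roi.name, mean_suv=st.mean,
                                 max_suv=st.max, sd_suv=st.sd,
                                 cov_percent=st.cov_percent, n_voxels=st.n_voxels))
    roi_df = pd.DataFrame(roi_rows)
    _write_csv(roi_df, out / "roi_stats.csv")

    from .voxels import exceedance_summary, paired_voxel_test
    rows = []
    for p, tr in trs:
        diff = voxel_difference(tr, rr)
        summ = exceedance_summary(diff, qsd, rr,
                                  relative_floor_suv=relative_floor_suv)
        pval = paired_voxel_test(tr, rr)
        mask = significance_mask(diff, qsd)
        mask.to_nifti(out / (p.stem + "_mask.nii"), sidecar={"qsd_suv": qsd.value})
        rows.append(dict(volume=p.name, p_value=pval, **summ))
    vox_df = pd.DataFrame(rows)
    _write_csv(vox_df, out / "voxel_analysis.csv")
    manifest = dict(software="petac", version=__version__, qsd_suv=qsd.value,
                    reference=str(rr_path), n_tests=len(trs))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
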