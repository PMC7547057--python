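"""Region-of-interest statistics: SUV mean/max/SD, COV, and the FBP-vs-IR
paired COV comparison.

ROIs are 2-D circles on a named axial slice, membership by voxel-center
inclusion (a center exactly at the radius counts as inside). The noise
proxy is the SUV coefficient of variation, COV = SD / mean x 100, with the
sample SD (n - 1 denominator). For each acquisition, the COV difference
between the FBP and the matched IR dataset is dCOV = COV_FBP - COV_IR
(positive means FBP is noisier), and matched pairs across the grid are
compared with a two-sided paired t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ROIError
from .phantom import PhantomSpec
from .volume import ImageVolume

ROI_STATISTICS = ("mean", "max")


@dataclass(frozen=True)
class ROISpec:
    """A circular 2-D ROI on one axial slice, in voxel coordinates.

    ``statistic`` names the statistic of record: ``max`` for lesions (the
    conventional lesional metric, less sensitive to partial volume),
    ``mean`` elsewhere.
    """

    name: str
    slice_index: int
    center: tuple[float, float]
    radius_mm: float
    statistic: str = "mean"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ROIError(f"ROI {self.name!r}: nonpositive radius {self.radius_mm}")
        if self.statistic not in ROI_STATISTICS:
            raise ROIError(f"ROI {self.name!r}: unknown statistic {self.statistic!r}")

    def mask(self, volume: ImageVolume) -> np.ndarray:
        """Boolean in-plane mask; validates the circle lies inside the volume."""
        nx, ny, nz = volume.shape
        sx, sy, _ = volume.spacing
        k = self.slice_index
        if not (0 <= k < nz):
            raise ROIError(f"ROI {self.name!r}: slice {k} outside volume (nz={nz})")
        cx, cy = self.center
        if (cx - self.radius_mm / sx < 0 or cx + self.radius_mm / sx > nx - 1
                or cy - self.radius_mm / sy < 0 or cy + self.radius_mm / sy > ny - 1):
            raise ROIError(f"ROI {self.name!r}: circle extends outside the volume")
        ix = (np.arange(nx)[:, None] - cx) * sx
        iy = (np.arange(ny)[None, :] - cy) * sy
        return ix ** 2 + iy ** 2 <= self.radius_mm ** 2 + 1e-9


@dataclass(frozen=True)
class ROIStats:
    mean: float
    max: float
    sd: float
    cov_percent: float
    n_voxels: int


def roi_stats(volume: ImageVolume, roi: ROISpec) -> ROIStats:
    """Mean / max / sample-SD / COV of SUV over the in-ROI voxels."""
    volume.require_unit("SUV")
    m = roi.mask(volume)
    vals = volume.values[:, :, roi.slice_index][m]
    if vals.size < 2:
        raise ROIError(f"ROI {roi.name!r} contains {vals.size} voxel(s); need >= 2")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mean <= 0:
        raise ROIError(f"ROI {roi.name!r}: mean SUV {mean:g} <= 0, COV undefined")
    return ROIStats(mean=mean, max=float(vals.max()), sd=sd,
                    cov_percent=suv_cov(sd, mean), n_voxels=int(vals.size))


def suv_cov(sd: float, mean: float) -> float:
    """SUV coefficient of variation (%): SD / mean x 100."""
    if mean <= 0:
        raise ROIError(f"COV undefined for mean {mean:g} <= 0")
    return sd / mean * 100.0


def delta_cov(cov_fbp: float, cov_ir: float) -> float:
    """COV_FBP - COV_IR for a matched acquisition pair; positive = FBP noisier."""
    return cov_fbp - cov_ir


@dataclass(frozen=True)
class PairedCovResult:
    """Paired t test of matched FBP/IR COVs plus the dCOV summary row."""

    n_pairs: int
    min: float
    median: float
    mean: float
    max: float
    sd: float
    t_statistic: float
    p_value: float
    degenerate: bool


def paired_cov_test(fbp_covs, ir_covs) -> PairedCovResult:
    """Two-sided paired t test of matched COV lists + dCOV summary.

    Zero difference variance is a defined degenerate outcome (p = NaN,
    flagged), not an exception, so a study with identical pairs still
    reports its summary row.
    """
    fbp = np.asarray(fbp_covs, dtype=float)
    ir = np.asarray(ir_covs, dtype=float)
    if fbp.shape != ir.shape or fbp.ndim != 1:
        raise ValueError(f"matched lists required, got shapes {fbp.shape} vs {ir.shape}")
    if fbp.size < 2:
        raise ValueError(f"need >= 2 matched pairs, got {fbp.size}")
    d = fbp - ir
    degenerate = bool(np.allclose(d, d[0]))
    if degenerate:
        t, p = math.nan, math.nan
    else:
        t, p = stats.ttest_rel(fbp, ir)
    return PairedCovResult(
        n_pairs=int(d.size),
        min=float(d.min()), median=float(np.median(d)),
        mean=float(d.mean()), max=float(d.max()), sd=float(d.std(ddof=1)),
        t_statistic=float(t), p_value=float(p), degenerate=degenerate,
    )


# ----------------------------------------------------------------------
def default_rois(spec: PhantomSpec) -> list[ROISpec]:
    """Default ROI placements derived from the phantom geometry.

    Liver (r 15 mm, mean), soft tissue (r 10 mm, mean), soft tissue in the
    beam-hardening corridor (r 8 mm, mean) and the lung tumour (r 8.5 mm,
    max), each on the axial slice through its target structure.
    """

    def vox(world_mm, axis):
        n = spec.shape[axis]
        s = spec.spacing_mm[axis]
        return world_mm / s + (n - 1) / 2.0

    def slice_of(z_mm):
        return int(round(vox(z_mm, 2)))

    tumour = next(c for c in spec.compartments if c.name == "tumour")
    tc = tumour.shape.center
    return [
        ROISpec("liver", slice_of(-35.0), (vox(-55.0, 0), vox(5.0, 1)), 15.0, "mean"),
        ROISpec("soft_tissue", slice_of(-50.0), (vox(40.0, 0), vox(-85.0, 1)), 10.0, "mean"),
        ROISpec("beam_hardening_soft_tissue", slice_of(-35.0),
                (vox(75.0, 0), vox(78.0, 1)), 8.0, "mean"),
        ROISpec("tumour", slice_of(tc[2]), (vox(tc[0], 0), vox(tc[1], 1)),
                tumour.shape.radius, "max"),
    ]


def load_rois(path: str | Path) -> list[ROISpec]:
    """Read ROI specifications from YAML/JSON (a list of mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    rois = []
    for item in raw:
        rois.append(ROISpec(
            name=item["name"], slice_index=int(item["slice_index"]),
            center=(float(item["center"][0]), float(item["center"][1])),
            radius_mm=float(item["radius_mm"]),
            statistic=item.get("statistic", "mean"),
        ))
    return rois


def save_rois(rois: list[ROISpec], path: str | Path) -> Path:
    path = Path(path)
    payload = [dict(name=r.name, slice_index=r.slice_index,
                    center=list(r.center), radius_mm=r.radius_mm,
                    statistic=r.statistic) for r in rois]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


# ----------------------------------------------------------------------
def roi_table(bundle, rois: list[ROISpec]) -> pd.DataFrame:
    """Per-entry ROI statistics for every reconstruction in a bundle."""
    rows = []
    for entry in bundle.entries:
        for roi in rois:
            st = roi_stats(entry.volume, roi)
            rows.append(dict(
                roi=roi.name, statistic=roi.statistic,
                mas=entry.protocol.mas, kvp=entry.protocol.kvp,
                pitch=entry.protocol.pitch, algorithm=entry.protocol.algorithm,
                ctdi_mgy=round(entry.ctdi_mgy, 1),
                is_reference=entry.is_reference,
                mean_suv=st.mean, max_suv=st.max, sd_suv=st.sd,
                cov_percent=st.cov_percent, n_voxels=st.n_voxels,
                statistic_of_record=st.max if roi.statistic == "max" else st.mean,
            ))
    return pd.DataFrame(rows)


def delta_cov_table(bundle, rois: list[ROISpec]) -> pd.DataFrame:
    """Per-region dCOV summary + paired t test over matched FBP/IR pairs."""
    table = roi_table(bundle, rois)
    rows = []
    for roi in rois:
        sub = table[table.roi == roi.name]
        fbp = sub[sub.algorithm == "FBP"].set_index(["mas", "kvp", "pitch"]).cov_percent
        ir = sub[sub.algorithm == "IR"].set_index(["mas", "kvp", "pitch"]).cov_percent
        keys = fbp.index.intersection(ir.index)
        res = paired_cov_test(fbp.loc[keys].to_numpy(), ir.loc[keys].to_numpy())
        rows.append(dict(roi=roi.name, n_pairs=res.n_pairs,
                         dcov_min=res.min, dcov_median=res.median,
                         dcov_mean=res.mean, dcov_max=res.max,
                         t_statistic=res.t_statistic, p_value=res.p_value,
                         degenerate=res.degenerate))
    return pd.DataFrame(rows)
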