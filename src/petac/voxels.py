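"""Voxel-wise comparison of test reconstructions against the reference.

Every voxel of a test reconstruction (TR) is compared with its matching
voxel in the reference reconstruction (RR). The significance threshold is
the quantitatively significant difference (QSD): one sample SD of the SUV
inside the liver ROI of the RR. Per TR the analysis reports

* a two-sided paired t test over all support voxels,
* the percentage of support voxels whose absolute difference exceeds the
  QSD (strict inequality at the boundary),
* maximum and mean voxel difference as a percentage of the RR voxel value
  (restricted to RR voxels above a small floor to keep the ratio defined
  in zero-activity lung/air), and
* the binary significance mask of exceeding voxels.

The support is by default the phantom body (air excluded); whole-volume
mode is available since a physical analysis would include every voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PetacError
from .roi import ROISpec, roi_stats
from .volume import ImageVolume

DEFAULT_RELATIVE_FLOOR_SUV = 0.1


@dataclass(frozen=True)
class QSD:
    """The voxel-level significance threshold, in SUV."""

    value: float
    source_roi: str

    def __post_init__(self):
        if not self.value > 0:
            raise PetacError(
                f"QSD must be > 0, got {self.value:g} from ROI {self.source_roi!r} "
                "(constant reference region?)"
            )


def compute_qsd(rr: ImageVolume, liver_roi: ROISpec) -> QSD:
    """QSD = sample SD of the reference reconstruction inside the liver ROI."""
    st = roi_stats(rr, liver_roi)
    return QSD(value=st.sd, source_roi=liver_roi.name)


def voxel_difference(tr: ImageVolume, rr: ImageVolume) -> ImageVolume:
    """Signed per-voxel difference RR - TR (positive = TR underestimates)."""
    tr.require_unit("SUV")
    rr.require_unit("SUV")
    rr.require_same_grid(tr)
    return ImageVolume(rr.values - tr.values, rr.spacing, "SUV_DELTA",
                       label=f"diff {rr.label!r} - {tr.label!r}")


def paired_voxel_test(tr: ImageVolume, rr: ImageVolume,
                      support_mask: np.ndarray | None = None) -> float:
    """Two-sided paired t test over support voxels; NaN when TR == RR.

    The degenerate zero-variance case (a reconstruction compared with
    itself) returns NaN rather than raising, so full-grid sweeps that
    include the reference entry complete cleanly.
    """
    rr.require_same_grid(tr)
    if support_mask is None:
        support_mask = np.ones(rr.shape, dtype=bool)
    a = tr.values[support_mask]
    b = rr.values[support_mask]
    if a.size < 2:
        raise PetacError(f"paired voxel test needs >= 2 support voxels, got {a.size}")
    d = a - b
    if float(d.std()) == 0.0:
        return math.nan
    _, p = stats.ttest_rel(a, b)
    return float(p)


def significance_mask(diff: ImageVolume, qsd: QSD) -> ImageVolume:
    """Binary volume of voxels with |RR - TR| strictly greater than the QSD."""
    mask = (np.abs(diff.values) > qsd.value).astype(np.float64)
    return ImageVolume(mask, diff.spacing, "MASK",
                       label=f"|diff| > QSD({qsd.value:.4g})")


def exceedance_summary(diff: ImageVolume, qsd: QSD,
                       rr: ImageVolume,
                       support_mask: np.ndarray | None = None,
                       relative_floor_suv: float = DEFAULT_RELATIVE_FLOOR_SUV) -> dict:
    """Exceedance percentage and max/mean relative voxel differences.

    Percent exceedance counts support voxels with ``|RR - TR| > QSD``
    (strict). Max and mean differences are ``100 x (RR - TR) / RR`` over
    support voxels whose RR value exceeds ``relative_floor_suv``.
    """
    rr.require_same_grid(diff)
    if support_mask is None:
        support_mask = np.ones(rr.shape, dtype=bool)
    n_support = int(support_mask.sum())
    if n_support == 0:
        raise PetacError("empty support mask")
    d = diff.values[support_mask]
    exceed = np.abs(d) > qsd.value
    pct = 100.0 * exceed.sum() / n_support

    rv = rr.values[support_mask]
    ok = rv > relative_floor_suv
    if ok.any():
        rel = 100.0 * d[ok] / rv[ok]
        max_pct = float(rel.max())
        mean_pct = float(rel.mean())
    else:
        max_pct = mean_pct = math.nan
    return dict(
        percent_gt_qsd=float(pct),
        max_diff_percent=max_pct,
        mean_diff_percent=mean_pct,
        n_support=n_support,
        n_exceeding=int(exceed.sum()),
        relative_floor_suv=relative_floor_suv,
    )


@dataclass
class VoxelComparison:
    """One test-reconstruction row of the voxel analysis."""

    protocol: object
    ctdi_mgy: float
    p_value: float
    percent_gt_qsd: float
    max_diff_percent: float
    mean_diff_percent: float
    mask: ImageVolume
    n_support: int

    def __post_init__(self):
        if not (math.isnan(self.percent_gt_qsd)
                or 0.0 <= self.percent_gt_qsd <= 100.0):
            raise PetacError(f"exceedance percent out of range: {self.percent_gt_qsd}")


def compare_entry(entry, rr: ImageVolume, qsd: QSD,
                  support_mask: np.ndarray | None = None,
                  relative_floor_suv: float = DEFAULT_RELATIVE_FLOOR_SUV) -> VoxelComparison:
    diff = voxel_difference(entry.volume, rr)
    summ = exceedance_summary(diff, qsd, rr, support_mask, relative_floor_suv)
    p = paired_voxel_test(entry.volume, rr, support_mask)
    return VoxelComparison(
        protocol=entry.protocol, ctdi_mgy=entry.ctdi_mgy, p_value=p,
        percent_gt_qsd=summ["percent_gt_qsd"],
        max_diff_percent=summ["max_diff_percent"],
        mean_diff_percent=summ["mean_diff_percent"],
        mask=significance_mask(diff, qsd),
        n_support=summ["n_support"],
    )


def compare_bundle(bundle, qsd: QSD,
                   support: str = "body",
                   relative_floor_suv: float = DEFAULT_RELATIVE_FLOOR_SUV
                   ) -> tuple[pd.DataFrame, dict[str, ImageVolume]]:
    """Voxel comparison of every entry against the RR.

    ``support`` is ``"body"`` (phantom voxels only, the default) or
    ``"all"`` (every voxel in the volume). The reference entry yields the
    degenerate self-comparison row (NaN statistics, empty mask). Returns
    the per-entry table and the significance masks keyed by protocol.
    """
    if support == "body":
        mask = bundle.body_mask()
    elif support == "all":
        mask = np.ones(bundle.ground_truth.shape, dtype=bool)
    else:
        raise ValueError(f"support must be 'body' or 'all', got {support!r}")
    rr = bundle.reference.volume
    rows = []
    masks: dict[str, ImageVolume] = {}
    for entry in bundle.entries:
        cmp = compare_entry(entry, rr, qsd, mask, relative_floor_suv)
        is_ref = entry.is_reference
        rows.append(dict(
            mas=entry.protocol.mas, kvp=entry.protocol.kvp,
            pitch=entry.protocol.pitch, algorithm=entry.protocol.algorithm,
            ctdi_mgy=round(entry.ctdi_mgy, 1),
            percent_gt_qsd=math.nan if is_ref else cmp.percent_gt_qsd,
            max_diff_percent=math.nan if is_ref else cmp.max_diff_percent,
            mean_diff_percent=math.nan if is_ref else cmp.mean_diff_percent,
            p_value=cmp.p_value,
            is_reference=is_ref,
        ))
        masks[str(entry.protocol)] = cmp.mask
    return pd.DataFrame(rows), masks


def spatial_localization_score(mask: ImageVolume,
                               regions: dict[str, np.ndarray],
                               support_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-region exceedance rate and enrichment relative to the global rate.

    ``regions`` maps region names to boolean volumes on the mask grid
    (regions may overlap). Enrichment = region rate / global rate over the
    support; NaN where the global rate is zero.
    """
    m = mask.values > 0.5
    if support_mask is None:
        support_mask = np.ones(m.shape, dtype=bool)
    if support_mask.shape != m.shape:
        raise PetacError(f"support grid {support_mask.shape} != mask grid {m.shape}")
    global_n = int(support_mask.sum())
    global_rate = m[support_mask].mean() if global_n else math.nan
    rows = []
    for name, region in regions.items():
        if region.shape != m.shape:
            raise PetacError(f"region {name!r} grid {region.shape} != mask grid {m.shape}")
        r = region & support_mask
        n = int(r.sum())
        rate = float(m[r].mean()) if n else math.nan
        enrich = rate / global_rate if (n and global_rate > 0) else math.nan
        rows.append(dict(region=name, n_voxels=n, exceedance_rate=rate,
                         enrichment=enrich))
    out = pd.DataFrame(rows)
    out.attrs["global_rate"] = float(global_rate)
    return out
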