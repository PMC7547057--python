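"""Voxel volumes with physical spacing and a unit tag.

``ImageVolume`` is the common currency of the pipeline: every simulated or
loaded dataset is a 3-D scalar field with millimetre spacing and one of a
small set of unit tags (SUV activity, CT numbers in HU, linear attenuation
at 511 keV in 1/cm, raw counts, a binary mask, or a signed SUV difference).
Volumes are only ever combined when shape and spacing match exactly; nothing
in the pipeline resamples silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, UnitError

#: Recognised unit tags.
UNITS = ("SUV", "HU", "MU_511", "COUNTS", "MASK", "SUV_DELTA")

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class ImageVolume:
    """A 3-D scalar field with voxel spacing (mm) and a unit tag.

    The array is indexed ``values[x, y, z]``; axial slices are
    ``values[:, :, k]``. World coordinates sit at voxel centers with the
    origin at the grid center.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        self._check_bounds()

    def _check_bounds(self) -> None:
        v = self.values
        if self.unit == "HU":
            if v.min() < HU_MIN - 1e-9 or v.max() > HU_MAX + 1e-9:
                raise ValueError(
                    f"HU volume out of bounds [{HU_MIN}, {HU_MAX}]: "
                    f"range [{v.min():.1f}, {v.max():.1f}]"
                )
        elif self.unit in ("MU_511", "SUV", "COUNTS"):
            if v.min() < -1e-9:
                raise ValueError(f"{self.unit} volume must be nonnegative (min={v.min():.4g})")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise UnitError(f"expected a {unit} volume, got {self.unit} ({self.label!r})")

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "ImageVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing} "
                f"({self.label!r}) vs {other.shape}@{other.spacing} ({other.label!r})"
            )

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    label: str | None = None) -> "ImageVolume":
        return ImageVolume(
            values=values,
            spacing=self.spacing,
            unit=self.unit if unit is None else unit,
            label=self.label if label is None else label,
        )

    def copy(self) -> "ImageVolume":
        return replace(self, values=self.values.copy())

    # ------------------------------------------------------------------
    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis, grid-centered."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing[axis]

    def block_downsample(self, factors: tuple[int, int, int]) -> "ImageVolume":
        """Average over non-overlapping blocks; factors must divide the shape."""
        fx, fy, fz = (int(f) for f in factors)
        nx, ny, nz = self.shape
        if nx % fx or ny % fy or nz % fz:
            raise ValueError(f"factors {factors} do not divide shape {self.shape}")
        v = self.values.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz)
        out = v.mean(axis=(1, 3, 5))
        return ImageVolume(out, tuple(s * f for s, f in zip(self.spacing, (fx, fy, fz))),
                           self.unit, self.label)

    # ------------------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        for i in range(3):
            aff[i, 3] = -(self.shape[i] - 1) / 2.0 * self.spacing[i]
        return aff

    def to_nifti(self, path: str | Path, sidecar: dict | None = None) -> Path:
        """Write as NIfTI-1 plus a JSON sidecar holding the unit tag and metadata."""
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))
        meta = {"unit": self.unit, "label": self.label, "spacing_mm": list(self.spacing)}
        if sidecar:
            meta.update(sidecar)
        side = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
            else path.with_suffix(".json")
        side.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, unit: str | None = None) -> "ImageVolume":
        """Load a NIfTI volume; the unit tag comes from the sidecar unless given."""
        path = Path(path)
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        label = path.stem
        if unit is None:
            side = path.with_suffix(".json")
            if side.exists():
                meta = json.loads(side.read_text())
                unit = meta.get("unit", "SUV")
                label = meta.get("label", label)
            else:
                unit = "SUV"
        return cls(data, spacing, unit, label=label)
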