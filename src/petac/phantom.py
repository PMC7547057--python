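"""Digital anthropomorphic torso phantom.

The phantom emulates a fillable torso phantom with arm-like lateral
attenuators: an elliptic soft-tissue torso containing two air-filled lungs,
a heart, a liver, a dense spine insert, and a small spherical "tumour" in
the right lung. Compartment activities are prescribed in SUV (soft tissue
1.0, heart 4.0, liver 2.5, tumour 4.0; lungs and spine hold no activity)
and CT numbers in HU. Two soft-tissue cylinders lateral to the torso stand
in for a patient's arms: they attenuate but carry no activity.

Geometry is parametric (ellipsoids, cylinders, spheres) in world
millimetres, so the same phantom can be rasterized at any grid size and
spacing. Rasterization is voxel-center inclusion; compartments listed later
override earlier ones, so the rasterized compartments are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .errors import CompartmentError
from .volume import ImageVolume

AIR_HU = -1000.0


# ----------------------------------------------------------------------
# Parametric geometry (world mm, origin at grid center)
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, X, Y, Z):
        cx, cy, cz = self.center
        a, b, c = self.semi_axes
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0

    def bounds(self):
        c = np.asarray(self.center)
        s = np.asarray(self.semi_axes)
        return np.stack([c - s, c + s])


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, X, Y, Z):
        cx, cy, cz = self.center
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= self.radius ** 2

    def bounds(self):
        c = np.asarray(self.center)
        return np.stack([c - self.radius, c + self.radius])


@dataclass(frozen=True)
class EllipticCylinder:
    """Elliptic cylinder along z; ``z_range=None`` spans the whole grid."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    z_range: Optional[tuple[float, float]] = None

    def contains(self, X, Y, Z):
        cx, cy = self.center
        a, b = self.semi_axes
        inside = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
        if self.z_range is not None:
            z0, z1 = self.z_range
            inside = inside & (Z >= z0) & (Z <= z1)
        return inside

    def bounds(self):
        cx, cy = self.center
        a, b = self.semi_axes
        z0, z1 = self.z_range if self.z_range is not None else (-np.inf, np.inf)
        return np.array([[cx - a, cy - b, z0], [cx + a, cy + b, z1]])


@dataclass(frozen=True)
class Cylinder(EllipticCylinder):
    """Circular cylinder along z."""

    def __init__(self, center, radius, z_range=None):
        super().__init__(center=center, semi_axes=(radius, radius), z_range=z_range)


Shape = Union[Ellipsoid, Sphere, EllipticCylinder]


@dataclass(frozen=True)
class Compartment:
    name: str
    shape: Shape
    suv: float
    hu: float


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PhantomSpec:
    """Grid plus an ordered compartment list (later entries override earlier).

    ``shape``/``spacing_mm`` describe the PET grid; the CT grid refines it by
    ``ct_refine`` along every axis.
    """

    shape: tuple[int, int, int] = (128, 128, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    compartments: tuple[Compartment, ...] = ()
    ct_refine: int = 2
    body_name: str = "torso"
    tumour_diameter_mm: float = 17.0

    @property
    def ct_shape(self) -> tuple[int, int, int]:
        return tuple(int(n * self.ct_refine) for n in self.shape)

    @property
    def ct_spacing_mm(self) -> tuple[float, float, float]:
        return tuple(s / self.ct_refine for s in self.spacing_mm)

    def extent_mm(self) -> np.ndarray:
        """Half-extent of the field of view along each axis."""
        return np.array([n * s / 2.0 for n, s in zip(self.shape, self.spacing_mm)])


def default_phantom(shape=(128, 128, 40), spacing_mm=(4.0, 4.0, 4.0),
                    tumour_diameter_mm: float = 17.0,
                    tumour_suv: float = 4.0) -> PhantomSpec:
    """The default torso phantom.

    Compartment SUVs: soft tissue 1.0, heart 4.0, liver 2.5, lung tumour 4.0;
    no activity in lungs, spine, or arm attenuators. Patient right is -x,
    posterior is +y, cranial is +z. All positions in mm.
    """
    r = tumour_diameter_mm / 2.0
    comps = (
        Compartment("torso", EllipticCylinder((0.0, 0.0), (150.0, 105.0)), 1.0, 40.0),
        Compartment("lung_right", Ellipsoid((-58.0, -8.0, 35.0), (45.0, 62.0, 42.0)), 0.0, -750.0),
        Compartment("lung_left", Ellipsoid((58.0, -8.0, 35.0), (45.0, 62.0, 42.0)), 0.0, -750.0),
        Compartment("heart", Ellipsoid((15.0, -25.0, 35.0), (32.0, 32.0, 28.0)), 4.0, 45.0),
        Compartment("liver", Ellipsoid((-55.0, 5.0, -35.0), (65.0, 62.0, 42.0)), 2.5, 55.0),
        Compartment("tumour", Sphere((-60.0, -15.0, 42.0), r), tumour_suv, 30.0),
        Compartment("spine", Cylinder((0.0, 78.0), 14.0), 0.0, 700.0),
        Compartment("arm_right", Cylinder((-192.0, 0.0), 38.0), 0.0, 40.0),
        Compartment("arm_left", Cylinder((192.0, 0.0), 38.0), 0.0, 40.0),
    )
    return PhantomSpec(shape=tuple(shape), spacing_mm=tuple(spacing_mm),
                       compartments=comps, tumour_diameter_mm=tumour_diameter_mm)


# ----------------------------------------------------------------------
def _grid_coords(shape, spacing):
    xs = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * spacing[0]
    ys = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * spacing[1]
    zs = (np.arange(shape[2]) - (shape[2] - 1) / 2.0) * spacing[2]
    return xs[:, None, None], ys[None, :, None], zs[None, None, :]


def _check_fits(spec: PhantomSpec, comp: Compartment) -> None:
    half = spec.extent_mm()
    lo, hi = comp.shape.bounds()
    lo = np.where(np.isinf(lo), -half, lo)
    hi = np.where(np.isinf(hi), half, hi)
    if np.any(lo < -half - 1e-9) or np.any(hi > half + 1e-9):
        raise CompartmentError(
            f"compartment {comp.name!r} extends outside the grid "
            f"(bounds x/y/z {np.stack([lo, hi]).T.tolist()}, half-extent {half.tolist()})"
        )


def compartment_masks(spec: PhantomSpec, shape=None, spacing=None) -> dict[str, np.ndarray]:
    """Rasterize each compartment to a boolean mask; later compartments override."""
    shape = spec.shape if shape is None else shape
    spacing = spec.spacing_mm if spacing is None else spacing
    X, Y, Z = _grid_coords(shape, spacing)
    masks: dict[str, np.ndarray] = {}
    for comp in spec.compartments:
        _check_fits(spec, comp)
        m = np.asarray(comp.shape.contains(X, Y, Z))
        masks[comp.name] = np.broadcast_to(m, shape).copy()
    # enforce disjointness: later definitions win
    names = list(masks)
    for i, name in enumerate(names):
        for later in names[i + 1:]:
            masks[name] &= ~masks[later]
    return masks


def rasterize(spec: PhantomSpec, shape=None, spacing=None):
    """Return (suv, hu) arrays for the phantom on the requested grid."""
    shape = spec.shape if shape is None else shape
    spacing = spec.spacing_mm if spacing is None else spacing
    masks = compartment_masks(spec, shape, spacing)
    suv = np.zeros(shape, dtype=np.float64)
    hu = np.full(shape, AIR_HU, dtype=np.float64)
    for comp in spec.compartments:
        m = masks[comp.name]
        suv[m] = comp.suv
        hu[m] = comp.hu
    return suv, hu


def build_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume]:
    """Rasterize the phantom: activity on the PET grid, attenuation on the CT grid.

    Voxel values equal the compartment prescriptions exactly (no noise).
    """
    if not spec.compartments:
        raise ValueError("phantom spec has no compartments")
    suv, _ = rasterize(spec, spec.shape, spec.spacing_mm)
    _, hu = rasterize(spec, spec.ct_shape, spec.ct_spacing_mm)
    activity = ImageVolume(suv, spec.spacing_mm, "SUV", label="phantom activity")
    attenuation = ImageVolume(hu, spec.ct_spacing_mm, "HU", label="phantom attenuation")
    return activity, attenuation


def body_mask(spec: PhantomSpec, shape=None, spacing=None) -> np.ndarray:
    """Voxels inside the phantom body (the torso outline, organs included)."""
    shape = spec.shape if shape is None else shape
    spacing = spec.spacing_mm if spacing is None else spacing
    body = next(c for c in spec.compartments if c.name == spec.body_name)
    X, Y, Z = _grid_coords(shape, spacing)
    return np.broadcast_to(np.asarray(body.shape.contains(X, Y, Z)), shape).copy()


def analysis_regions(spec: PhantomSpec, shape=None, spacing=None,
                     high_activity_suv: float = 2.0,
                     interface_hu_step: float = 150.0,
                     interface_shell_voxels: int = 2,
                     corridor_halfwidth_mm: float = 22.0) -> dict[str, np.ndarray]:
    """Label masks for spatial-localization scoring of exceedance maps.

    Regions (all restricted to the body; they may overlap, except
    ``background`` which is the remainder):

    - ``high_activity``: compartments with SUV >= ``high_activity_suv``;
    - ``interface``: tissue voxels within ``interface_shell_voxels`` of an
      internal CT-density step larger than ``interface_hu_step`` HU
      (lung-tissue, bone-tissue). The external body-air outline and the
      air-like side of the step are excluded: no emission originates there,
      so no SUV difference can be observed there;
    - ``beam_hardening``: the lateral corridor through the spine at arm
      height, where dense chords between arms and spine cross;
    - ``background``: body voxels in none of the above.
    """
    shape = spec.shape if shape is None else shape
    spacing = spec.spacing_mm if spacing is None else spacing
    masks = compartment_masks(spec, shape, spacing)
    body = body_mask(spec, shape, spacing)
    _, hu = rasterize(spec, shape, spacing)

    high = np.zeros(shape, dtype=bool)
    for comp in spec.compartments:
        if comp.suv >= high_activity_suv:
            high |= masks[comp.name]

    edge = np.zeros(shape, dtype=bool)
    for axis in range(3):
        d = np.abs(np.diff(hu, axis=axis)) > interface_hu_step
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        edge[tuple(sl_lo)] |= d
        edge[tuple(sl_hi)] |= d
    if interface_shell_voxels > 1:
        edge = ndimage.binary_dilation(edge, iterations=interface_shell_voxels - 1)
    outline = ndimage.binary_dilation(~body, iterations=interface_shell_voxels) & body
    tissue = hu > -300.0
    interface = edge & body & ~outline & tissue

    spine = next(c for c in spec.compartments if c.name == "spine")
    y_spine = spine.shape.center[1]
    _, Y, _ = _grid_coords(shape, spacing)
    corridor = (np.abs(Y - y_spine) <= corridor_halfwidth_mm) & body & ~masks["spine"]
    corridor = np.broadcast_to(corridor, shape).copy()

    background = body & ~high & ~interface & ~corridor
    return {
        "high_activity": high & body,
        "interface": interface,
        "beam_hardening": corridor,
        "background": background,
        "body": body,
    }
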