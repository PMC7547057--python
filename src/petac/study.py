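"""Study orchestration: phantom -> one PET acquisition -> 48 reconstructions.

``generate_study`` builds the phantom, simulates the single emission
dataset through the true attenuation, then for every CT protocol in the
grid simulates a CT dataset, converts it to a 511-keV attenuation map, and
reconstructs the shared emission data with that map. The result is a
``StudyBundle``: the reference reconstruction (RR, from the reference
protocol's AC map) plus all test reconstructions (TRs) on one grid, with
per-entry protocol and CTDI.

Randomness derives from one master seed: ``SeedSequence(seed)`` is spawned
into one child per stage — child 0 drives the PET Poisson sample, child
``i + 1`` drives the CT simulation of protocol ``i`` in grid order — so a
bundle is bit-identical for a given seed and protocol list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct import (CTSimParams, DEFAULT_CT_PARAMS, beam_hardening_artifact,
                 hu_to_mu, simulate_ct)
from .errors import ProtocolError
from .pet import DEFAULT_COUNTS_PER_SLICE, reconstruct_osem, simulate_pet
from .phantom import PhantomSpec, body_mask, build_phantom, default_phantom
from .protocols import CTProtocol, REFERENCE_PROTOCOL, ctdi_model, default_protocols
from .volume import ImageVolume

DEFAULT_AC_SMOOTH_FWHM_MM = 6.0


@dataclass
class StudyEntry:
    protocol: CTProtocol
    ctdi_mgy: float
    volume: ImageVolume
    is_reference: bool = False


@dataclass
class StudyBundle:
    """All reconstructions of one simulated study on a shared grid."""

    entries: list[StudyEntry]
    ground_truth: ImageVolume
    true_mu: ImageVolume
    spec: PhantomSpec
    seed: int
    counts_target: float

    def __post_init__(self):
        refs = [e for e in self.entries if e.is_reference]
        if len(refs) != 1:
            raise ProtocolError(f"expected exactly one reference entry, found {len(refs)}")
        for e in self.entries:
            if e.ctdi_mgy <= 0:
                raise ProtocolError(f"nonpositive CTDI for {e.protocol}")
            e.volume.require_same_grid(self.ground_truth)

    @property
    def reference(self) -> StudyEntry:
        return next(e for e in self.entries if e.is_reference)

    @property
    def tests(self) -> list[StudyEntry]:
        return [e for e in self.entries if not e.is_reference]

    def body_mask(self) -> np.ndarray:
        return body_mask(self.spec)


def _smooth_mu(mu: ImageVolume, fwhm_mm: float) -> ImageVolume:
    if fwhm_mm <= 0:
        return mu
    sigma_vox = [fwhm_mm / 2.3548 / s for s in mu.spacing]
    sm = ndimage.gaussian_filter(mu.values, sigma=sigma_vox)
    return mu.with_values(np.clip(sm, 0.0, None))


def make_ac_map(ct: ImageVolume, pet_shape, ac_smooth_fwhm_mm: float = DEFAULT_AC_SMOOTH_FWHM_MM) -> ImageVolume:
    """CT dataset -> attenuation map on the PET grid.

    The CT volume is block-averaged down to the PET grid, converted with
    the bilinear HU->mu map, then smoothed toward PET resolution the way a
    scanner prepares its AC map.
    """
    factors = tuple(int(round(c / p)) for c, p in zip(ct.shape, pet_shape))
    if any(f < 1 for f in factors) or tuple(c // f for c, f in zip(ct.shape, factors)) != tuple(pet_shape):
        raise ValueError(f"CT grid {ct.shape} is not an integer refinement of PET grid {pet_shape}")
    down = ct.block_downsample(factors) if factors != (1, 1, 1) else ct
    mu = hu_to_mu(down)
    return _smooth_mu(mu, ac_smooth_fwhm_mm)


def generate_study(spec: PhantomSpec | None = None,
                   protocols: list[CTProtocol] | None = None,
                   seed: int = 0,
                   reference: CTProtocol = REFERENCE_PROTOCOL,
                   counts_target: float = DEFAULT_COUNTS_PER_SLICE,
                   ct_params: CTSimParams = DEFAULT_CT_PARAMS,
                   iterations: int = 3, subsets: int = 3,
                   ac_smooth_fwhm_mm: float = DEFAULT_AC_SMOOTH_FWHM_MM,
                   poisson: bool = True) -> StudyBundle:
    """Run the full simulated study and return a :class:`StudyBundle`.

    Exactly one protocol in the list must equal ``reference``. The emission
    sinogram is generated once and shared by every reconstruction; the SUV
    scale is calibrated so the reconstruction with the true attenuation map
    has the same whole-phantom (body) mean as the ground truth.
    """
    spec = default_phantom() if spec is None else spec
    protocols = default_protocols() if protocols is None else list(protocols)
    if not protocols:
        raise ProtocolError("empty protocol list")
    n_ref = sum(p == reference for p in protocols)
    if n_ref != 1:
        raise ProtocolError(
            f"expected the reference protocol {reference} exactly once in the grid, found {n_ref}"
        )

    activity, attenuation_ct = build_phantom(spec)
    body = body_mask(spec)

    # true attenuation on the PET grid: crisp physics, no scanner smoothing
    factors = (spec.ct_refine,) * 3
    mu_true = hu_to_mu(attenuation_ct.block_downsample(factors))
    mu_true = mu_true.with_values(mu_true.values, label="true mu")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(protocols) + 1)

    sino = simulate_pet(activity, mu_true, counts_target=counts_target,
                        seed=children[0], poisson=poisson)

    # SUV calibration from the true-map reconstruction
    recon_true = reconstruct_osem(sino, mu_true, iterations=iterations, subsets=subsets)
    mean_true = float(recon_true.values[body].mean())
    scale = float(activity.values[body].mean()) / mean_true if mean_true > 0 else 1.0

    bh = beam_hardening_artifact(attenuation_ct) if ct_params.bh_hu > 0 else None

    entries: list[StudyEntry] = []
    for i, protocol in enumerate(protocols):
        ctdi = ctdi_model(protocol)
        ct = simulate_ct(attenuation_ct, protocol, seed=children[i + 1],
                         params=ct_params, ctdi=ctdi, bh_artifact=bh)
        mu_ac = make_ac_map(ct, spec.shape, ac_smooth_fwhm_mm)
        vol = reconstruct_osem(sino, mu_ac, iterations=iterations,
                               subsets=subsets, scale=scale)
        vol.label = f"PET <- AC {protocol}"
        entries.append(StudyEntry(protocol=protocol, ctdi_mgy=ctdi, volume=vol,
                                  is_reference=(protocol == reference)))

    return StudyBundle(entries=entries, ground_truth=activity, true_mu=mu_true,
                       spec=spec, seed=seed, counts_target=counts_target)
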