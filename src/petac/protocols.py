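"""CT acquisition protocols and the CTDI dose model.

The study grid enumerates tube current 15/25/40/50 mAs, tube voltage
80/100/120 kVp and pitch 0.671/0.828 — 24 acquisitions — each reconstructed
with both filtered back projection (FBP) and iterative reconstruction (IR),
yielding 48 CT datasets. The reference protocol is 50 mAs, 120 kVp,
pitch 0.828, IR.

The scanner-reported CT dose index (CTDI, mGy) is modelled as
``c(kVp) x mAs`` with per-voltage coefficients fitted by least squares to
the scanner's reported calibration table; at this scanner's reporting
precision CTDI does not depend on pitch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ProtocolError

CURRENTS_MAS = (15, 25, 40, 50)
VOLTAGES_KVP = (80, 100, 120)
PITCHES = (0.671, 0.828)
ALGORITHMS = ("FBP", "IR")

#: Scanner-reported CTDI (mGy) per (mAs, kVp); pitch-independent at the
#: scanner's 0.1 mGy reporting precision.
CTDI_TABLE: dict[tuple[int, int], float] = {
    (15, 80): 0.3, (25, 80): 0.5, (40, 80): 0.8, (50, 80): 0.9,
    (15, 100): 0.6, (25, 100): 1.0, (40, 100): 1.6, (50, 100): 2.0,
    (15, 120): 1.0, (25, 120): 1.6, (40, 120): 2.6, (50, 120): 3.3,
}


@dataclass(frozen=True)
class CTProtocol:
    """One CT acquisition + reconstruction: (mAs, kVp, pitch, algorithm)."""

    mas: float
    kvp: float
    pitch: float = 0.828
    algorithm: str = "FBP"
    ir_level: int = 3  # ordinal noise-suppression level of the IR surrogate

    def __post_init__(self):
        if self.mas < 0:
            raise ProtocolError(f"negative tube current: {self.mas} mAs")
        if self.algorithm not in ALGORITHMS:
            raise ProtocolError(f"unknown algorithm {self.algorithm!r}; expected FBP or IR")

    @property
    def acquisition(self) -> tuple[float, float, float]:
        """The acquisition key (mAs, kVp, pitch) shared by an FBP/IR pair."""
        return (self.mas, self.kvp, self.pitch)

    def __str__(self) -> str:
        return f"{self.mas:g}mAs/{self.kvp:g}kVp/p{self.pitch:g}/{self.algorithm}"


REFERENCE_PROTOCOL = CTProtocol(50, 120, 0.828, "IR")


def default_protocols() -> list[CTProtocol]:
    """The full 48-dataset grid (24 acquisitions x {FBP, IR})."""
    grid = []
    for mas in CURRENTS_MAS:
        for kvp in VOLTAGES_KVP:
            for pitch in PITCHES:
                for alg in ALGORITHMS:
                    grid.append(CTProtocol(mas, kvp, pitch, alg))
    return grid


@lru_cache(maxsize=8)
def _fit_coefficients(table_items: tuple) -> dict[float, float]:
    """Per-kVp dose coefficients c (mGy/mAs), least squares through the origin."""
    table = dict(table_items)
    coeffs: dict[float, float] = {}
    for kvp in sorted({k for _, k in table}):
        mas = np.array([m for m, k in table if k == kvp], dtype=float)
        dose = np.array([table[(m, k)] for m, k in table if k == kvp], dtype=float)
        coeffs[float(kvp)] = float(mas @ dose / (mas @ mas))
    return coeffs


def ctdi_model(protocol: CTProtocol, calibration: dict | None = None,
               extrapolate: bool = False) -> float:
    """CTDI (mGy) for a protocol: ``c(kVp) x mAs``, c calibrated per voltage.

    Voltages between calibrated values are interpolated linearly in c;
    voltages outside the calibrated range are rejected unless
    ``extrapolate`` is set. Zero exposure returns zero dose, and dose is
    monotone nondecreasing in mAs at fixed voltage.
    """
    table = CTDI_TABLE if calibration is None else calibration
    coeffs = _fit_coefficients(tuple(sorted(table.items())))
    kvps = np.array(sorted(coeffs))
    kvp = float(protocol.kvp)
    if kvp < kvps[0] or kvp > kvps[-1]:
        if not extrapolate:
            raise ProtocolError(
                f"voltage {kvp:g} kVp outside calibrated range "
                f"[{kvps[0]:g}, {kvps[-1]:g}]; pass extrapolate=True to allow"
            )
        kvp_clip = float(np.clip(kvp, kvps[0], kvps[-1]))
        c = float(np.interp(kvp_clip, kvps, [coeffs[k] for k in kvps]))
    else:
        c = float(np.interp(kvp, kvps, [coeffs[k] for k in kvps]))
    return c * float(protocol.mas)
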