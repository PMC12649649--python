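"""Acid-base and ventilation arithmetic linking blood chemistry to breathing rate.

The chemoreceptive drive onto the rhythm-generating network is set by arterial
CO2 and bicarbonate through a short chain of classical physiology:

* the Henderson-Hasselbalch equation relates pH, [HCO3-] and pCO2;
* alveolar ventilation follows from CO2 production and arterial pCO2;
* breaths per minute follow from ventilation and alveolar volume;
* the chemoreflex maps arterial pCO2 to a commanded respiratory rate through
  a piecewise-linear response with two thresholds.

All functions are pure and operate on floats; :class:`PhysioState` bundles a
consistent snapshot, and :func:`physiology_table` reproduces the reference
operating table (physiological point plus the CO2-production and bicarbonate
variation ranges) used to configure the chemosensory spike-train frequency.

Units follow clinical convention: pCO2 in mmHg, [HCO3-] in mmol/L, CO2
production in mL/min, alveolar ventilation in L/min, alveolar volume in L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PKA",
    "ALPHA_CO2",
    "VENT_UNIT_CONV",
    "PhysioState",
    "ChemoreflexMap",
    "ph_from_hh",
    "pco2_for_compensation",
    "alveolar_ventilation",
    "bpm_from_ventilation",
    "interval_ms",
    "freq_hz",
    "rtn_freq_from_vco2",
    "rtn_freq_from_hco3",
    "rr_from_paco2",
    "physiology_table",
]

#: Negative log dissociation constant of carbonic acid.
PKA = 6.1
#: CO2 solubility in plasma at 37 C, mmol/L per mmHg.
ALPHA_CO2 = 0.03
#: Unit-conversion constant between VCO2 (mL/min), VA (L/min) and pCO2 (mmHg).
VENT_UNIT_CONV = 0.863

# Physiological reference operating point.
_REF_HCO3 = 24.0       # mmol/L
_REF_PACO2 = 40.1      # mmHg
_REF_VCO2 = 250.0      # mL/min
_REF_VA_VOL = 0.35     # L, alveolar volume per breath

# Plausibility windows; values outside trigger a warning, never an error.
_PACO2_WINDOW = (10.0, 120.0)
_HCO3_WINDOW = (5.0, 50.0)


def _window_check(name: str, value: float, window: tuple[float, float]) -> None:
    lo, hi = window
    if not lo <= value <= hi:
        warnings.warn(
            f"{name}={value:g} outside the physiological window [{lo:g}, {hi:g}]",
            stacklevel=3,
        )


def ph_from_hh(hco3: float, pco2: float) -> float:
    """Blood pH from bicarbonate (mmol/L) and pCO2 (mmHg).

    Henderson-Hasselbalch: ``pH = pKa + log10([HCO3-] / (alpha * pCO2))``.
    """
    if not (hco3 > 0 and pco2 > 0):
        raise ValueError(f"hco3 and pco2 must be positive, got {hco3}, {pco2}")
    _window_check("pco2", pco2, _PACO2_WINDOW)
    return PKA + math.log10(hco3 / (ALPHA_CO2 * pco2))


def pco2_for_compensation(hco3: float, ph: float = 7.4) -> float:
    """pCO2 (mmHg) that compensates a given bicarbonate level at fixed pH.

    Exact algebraic inverse of :func:`ph_from_hh` in its second argument.
    """
    if hco3 <= 0:
        raise ValueError(f"hco3 must be positive, got {hco3}")
    _window_check("hco3", hco3, _HCO3_WINDOW)
    return hco3 / (ALPHA_CO2 * 10.0 ** (ph - PKA))


def alveolar_ventilation(vco2: float, paco2: float) -> float:
    """Alveolar ventilation (L/min) from CO2 production (mL/min) and PaCO2 (mmHg)."""
    if paco2 <= 0:
        raise ValueError(f"paco2 must be positive, got {paco2}")
    if vco2 < 0:
        raise ValueError(f"vco2 must be non-negative, got {vco2}")
    return VENT_UNIT_CONV * vco2 / paco2


def bpm_from_ventilation(va_dot: float, va_volume: float) -> float:
    """Breaths per minute from alveolar ventilation (L/min) and alveolar volume (L)."""
    if va_volume <= 0:
        raise ValueError(f"va_volume must be positive, got {va_volume}")
    return va_dot / va_volume


def interval_ms(bpm: float) -> float:
    """Interval between breaths in ms: one minute divided by the rate."""
    if bpm <= 0:
        raise ValueError(f"bpm must be positive for a finite interval, got {bpm}")
    return 60_000.0 / bpm


def freq_hz(bpm: float) -> float:
    """Breathing frequency in Hz."""
    return bpm / 60.0


def rtn_freq_from_vco2(vco2: float) -> float:
    """Chemosensory drive frequency (Hz) as a linear function of CO2 production.

    Condenses the ventilation chain at the physiological operating point
    (PaCO2 40.1 mmHg, alveolar volume 0.35 L): ``f = c1 * VCO2`` with
    ``c1 = 0.863 / (40.1 * 0.35 * 60)``.
    """
    if vco2 < 0:
        raise ValueError(f"vco2 must be non-negative, got {vco2}")
    c1 = VENT_UNIT_CONV / (_REF_PACO2 * _REF_VA_VOL * 60.0)
    return c1 * vco2


def rtn_freq_from_hco3(hco3: float, ph: float = 7.4) -> float:
    """Chemosensory drive frequency (Hz) as a hyperbolic function of bicarbonate.

    At fixed pH and CO2 production (250 mL/min), the compensating PaCO2 scales
    with [HCO3-], so the drive frequency is ``c2 / [HCO3-]`` with
    ``c2 = 0.863 * 250 * 0.03 * 10**(pH - 6.1) / (0.35 * 60)``.
    """
    if hco3 <= 0:
        raise ValueError(f"hco3 must be positive, got {hco3}")
    c2 = (
        VENT_UNIT_CONV * _REF_VCO2 * ALPHA_CO2 * 10.0 ** (ph - PKA)
        / (_REF_VA_VOL * 60.0)
    )
    return c2 / hco3


@dataclass(frozen=True)
class ChemoreflexMap:
    """Piecewise-linear PaCO2 -> respiratory-rate response at iso-oxic PO2 80 mmHg.

    Below ``t1`` the chemosensory population is silenced and breathing holds at
    the basal rate; between the two thresholds the response rises with slope
    ``s1``, above the second with the steeper slope ``s2``.  The intercepts make
    the map continuous at both breakpoints.
    """

    t1: float = 44.3            # mmHg, first threshold
    t2: float = 52.2            # mmHg, second threshold
    s1: float = 0.7             # bpm/mmHg on [t1, t2]
    s2: float = 1.5             # bpm/mmHg above t2
    basal_rr: float = 13.0      # bpm below t1
    intercept1: float = -18.01  # bpm
    intercept2: float = -59.77  # bpm

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"t1 must be below t2, got {self.t1} >= {self.t2}")
        for name, jump in (
            ("t1", self.s1 * self.t1 + self.intercept1 - self.basal_rr),
            ("t2", (self.s2 - self.s1) * self.t2 + self.intercept2 - self.intercept1),
        ):
            if abs(jump) > 0.01:
                raise ValueError(f"chemoreflex map discontinuous at {name}: jump {jump:.3f} bpm")


@dataclass
class RespiratoryCommand:
    """Outcome of one chemoreflex evaluation."""

    rr_bpm: float
    rtn_interval_ms: float
    rtn_silenced: bool


def rr_from_paco2(paco2: float, cmap: ChemoreflexMap | None = None) -> RespiratoryCommand:
    """Commanded respiratory rate (bpm) and drive interval (ms) for a PaCO2 reading.

    Below the first threshold the chemosensory drive is silenced and the basal
    rate is held; otherwise the appropriate linear branch applies.
    """
    if paco2 <= 0:
        raise ValueError(f"paco2 must be positive, got {paco2}")
    _window_check("paco2", paco2, _PACO2_WINDOW)
    m = cmap if cmap is not None else ChemoreflexMap()
    if paco2 < m.t1:
        rr = m.basal_rr
        silenced = True
    elif paco2 <= m.t2:
        rr = m.s1 * paco2 + m.intercept1
        silenced = False
    else:
        rr = m.s2 * paco2 + m.intercept2
        silenced = False
    return RespiratoryCommand(rr_bpm=rr, rtn_interval_ms=interval_ms(rr), rtn_silenced=silenced)


@dataclass
class PhysioState:
    """A consistent acid-base/ventilation snapshot derived from first principles.

    Build one with :meth:`from_vco2` (CO2-production variation at fixed blood
    chemistry) or :meth:`from_hco3` (bicarbonate variation at fixed pH and CO2
    production); all downstream quantities are chained at full precision.
    """

    hco3: float
    paco2: float
    vco2: float
    va_volume: float = _REF_VA_VOL
    pka: float = PKA
    alpha: float = ALPHA_CO2
    k_conv: float = VENT_UNIT_CONV
    ph: float = field(init=False)
    va_dot: float = field(init=False)
    bpm: float = field(init=False)
    interval: float = field(init=False)
    f: float = field(init=False)

    def __post_init__(self) -> None:
        self.ph = ph_from_hh(self.hco3, self.paco2)
        self.va_dot = alveolar_ventilation(self.vco2, self.paco2)
        self.bpm = bpm_from_ventilation(self.va_dot, self.va_volume)
        self.interval = interval_ms(self.bpm)
        self.f = freq_hz(self.bpm)

    @classmethod
    def from_vco2(cls, vco2: float, hco3: float = _REF_HCO3,
                  paco2: float = _REF_PACO2) -> "PhysioState":
        return cls(hco3=hco3, paco2=paco2, vco2=vco2)

    @classmethod
    def from_hco3(cls, hco3: float, ph: float = 7.4,
                  vco2: float = _REF_VCO2) -> "PhysioState":
        return cls(hco3=hco3, paco2=pco2_for_compensation(hco3, ph), vco2=vco2)


def physiology_table() -> pd.DataFrame:
    """Reference operating table: physiological point and both variation ranges.

    Returns one row per quantity with full-precision endpoints for the CO2
    production sweep (250 -> 620 mL/min) and the bicarbonate sweep
    (10 -> 24 mmol/L), chained through the ventilation equations.
    """
    phys = PhysioState.from_vco2(_REF_VCO2)
    v_hi = PhysioState.from_vco2(620.0)
    h_lo = PhysioState.from_hco3(10.0)
    h_hi = PhysioState.from_hco3(24.0)

    def rows(name, fn, fmt="{:.6g}"):
        return {
            "parameter": name,
            "physiological": fmt.format(fn(phys)),
            "vco2_250": fmt.format(fn(phys)),
            "vco2_620": fmt.format(fn(v_hi)),
            "hco3_10": fmt.format(fn(h_lo)),
            "hco3_24": fmt.format(fn(h_hi)),
        }

    table = [
        rows("pH", lambda s: s.ph),
        rows("HCO3 (mmol/L)", lambda s: s.hco3),
        rows("PaCO2 (mmHg)", lambda s: s.paco2),
        rows("VCO2 (mL/min)", lambda s: s.vco2),
        rows("VA_dot (L/min)", lambda s: s.va_dot),
        rows("VA (L)", lambda s: s.va_volume),
        rows("bpm (1/min)", lambda s: s.bpm),
        rows("interval (ms)", lambda s: s.interval),
        rows("RTN frequency (Hz)", lambda s: s.f),
    ]
    return pd.DataFrame(table)
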