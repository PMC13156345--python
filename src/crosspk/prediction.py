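"""Static drug-interaction and translational calculators.

Desk-scale predictors used when triaging a candidate precipitant before (or
after) a clinical study: steady-state accumulation, the mechanistic static
model for mechanism-based (time-dependent) CYP inhibition, NOAEL-to-human
dose conversion by body-surface-area scaling, constituent dose scaling for a
multi-capsule botanical product, and a luminal-concentration solubility
screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InactivationParameters",
    "KM_FACTORS",
    "accumulation_ratio",
    "constituent_dose",
    "hed_from_noael",
    "inhibitor_concentration_multiple_dose",
    "luminal_concentration",
    "msm_aucr_tdi",
]


def accumulation_ratio(t_half_h: float, tau_h: float) -> float:
    """Steady-state accumulation ratio 1/(1 − e^(−kτ)) with k = ln2/t_half.

    Strictly decreasing in the dosing interval τ, increasing in the
    half-life, and always > 1 for finite positive inputs.
    """
    if t_half_h <= 0 or tau_h <= 0:
        raise ValueError("t_half_h and tau_h must be > 0")
    k = math.log(2.0) / t_half_h
    return 1.0 / (1.0 - math.exp(-k * tau_h))


@dataclass(frozen=True)
class InactivationParameters:
    """Inputs of the static model for mechanism-based inhibition.

    ``fm``: fraction of the object drug's clearance through the inhibited
    enzyme; ``kinact``: maximal inactivation rate (1/h); ``ki``: inactivator
    concentration at half-maximal inactivation rate (same units as ``i``);
    ``i``: inhibitor concentration at the enzyme; ``kdeg``: first-order
    enzyme degradation (resynthesis turnover) rate (1/h).
    """

    fm: float
    kinact: float
    ki: float
    i: float
    kdeg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fm <= 1.0:
            raise ValueError("fm must lie in [0, 1]")
        if self.kinact <= 0 or self.ki <= 0 or self.kdeg <= 0:
            raise ValueError("kinact, ki and kdeg must be > 0")
        if self.i < 0:
            raise ValueError("inhibitor concentration must be >= 0")


def msm_aucr_tdi(p: InactivationParameters) -> float:
    """Predicted AUC ratio from the hepatic static model for time-dependent inhibition.

        AUCR = 1 / [ fm / (1 + kinact·I / (kdeg·(KI + I))) + (1 − fm) ]

    AUCR = 1 with no inhibitor or no sensitive pathway, and is bounded above
    by 1/(1 − fm); fm = 1 with unbounded inactivation returns +inf.
    """
    lam = p.kinact * p.i / (p.kdeg * (p.ki + p.i))
    denom = p.fm / (1.0 + lam) + (1.0 - p.fm)
    if denom == 0.0:
        return math.inf
    return 1.0 / denom


def inhibitor_concentration_multiple_dose(i_single: float, accumulation: float) -> float:
    """Scale a single-dose inhibitor concentration to steady state."""
    if i_single < 0 or accumulation < 1:
        raise ValueError("require i_single >= 0 and accumulation >= 1")
    return i_single * accumulation


#: FDA body-surface-area conversion factors (kg body weight / m²).
KM_FACTORS = {
    "mouse": 3.0,
    "hamster": 5.0,
    "rat": 6.0,
    "guinea pig": 8.0,
    "rabbit": 12.0,
    "monkey": 12.0,
    "dog": 20.0,
    "human": 37.0,
}


def hed_from_noael(dose_mg_per_kg: float, species: str) -> float:
    """Human-equivalent dose (mg/kg) from an animal NOAEL by BSA scaling.

    HED = dose × Km(species) / Km(human); linear in dose and the identity
    for human input.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    try:
        km = KM_FACTORS[species.lower()]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; supported: {sorted(KM_FACTORS)}"
        ) from None
    return dose_mg_per_kg * km / KM_FACTORS["human"]


def luminal_concentration(
    dose_mg: float,
    volume_mL: float = 250.0,
    solubility_mg_per_mL: float = 1.42,
) -> tuple[float, bool]:
    """Concentration of a dose dissolved in intestinal fluid and a solubility flag.

    Returns (dose/volume in mg/mL, concentration ≤ solubility).  The default
    volume is the regulatory 250-mL glass-of-water convention.
    """
    if dose_mg < 0 or volume_mL <= 0:
        raise ValueError("require dose_mg >= 0 and volume_mL > 0")
    conc = dose_mg / volume_mL
    return conc, conc <= solubility_mg_per_mL


def constituent_dose(per_capsule_mg: float, capsules_per_dose: float) -> float:
    """Milligrams of a constituent delivered per product dose."""
    if per_capsule_mg < 0 or capsules_per_dose < 0:
        raise ValueError("inputs must be >= 0")
    return per_capsule_mg * capsules_per_dose
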