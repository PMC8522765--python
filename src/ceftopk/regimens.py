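"""Ceftobiprole pediatric dosing rules.

Encodes the optimized age/renal-function dosing matrix derived from
model-based simulations, the three clinical studies' original regimens, and
expansion of a regimen into concrete infusion events with the 500 mg
per-dose cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pk3cmt import DoseEvent

__all__ = [
    "Regimen",
    "optimized_regimen",
    "study_regimen",
    "expand_doses",
    "policy_table",
    "renal_category_from_gfr_norm",
    "DOSE_CAP_MG",
    "LOW_WEIGHT_CUTOFF_KG",
]

DOSE_CAP_MG = 500.0
#: Neonates/infants <3 months below this weight receive 10 mg/kg instead of 15.
LOW_WEIGHT_CUTOFF_KG = 4.0


@dataclass(frozen=True)
class Regimen:
    """A weight-based repeated-infusion regimen."""

    dose_per_kg: float  # mg/kg
    interval: float  # h
    infusion_duration: float = 2.0  # h
    cap: float = DOSE_CAP_MG  # mg per dose

    def __post_init__(self) -> None:
        if min(self.dose_per_kg, self.interval, self.infusion_duration, self.cap) <= 0:
            raise ValueError("regimen fields must be positive")
        if 24.0 % self.interval != 0:
            raise ValueError("interval must divide 24 h")


def renal_category_from_gfr_norm(gfr_norm: float) -> str:
    """Renal-function category from BSA-normalized GFR (ml/min/1.73 m²).

    ≥50 is 'normal' (mild impairment is folded in), 30–<50 'moderate',
    10–<30 'severe'.  Below 10 is outside the supported (simulated) range.
    """
    if gfr_norm >= 50.0:
        return "normal"
    if gfr_norm >= 30.0:
        return "moderate"
    if gfr_norm >= 10.0:
        return "severe"
    raise ValueError("gfr_norm < 10 ml/min/1.73 m² is outside the supported range")


def optimized_regimen(age_years: float, weight_kg: float, gfr_norm: float) -> Regimen:
    """The optimized age/weight/renal-function regimen (all 2-h infusions).

    ========================  ==============  ==============  ==============
    Age group                 normal/mild     moderate        severe
    ========================  ==============  ==============  ==============
    birth to <3 mo            15 mg/kg q12h   15 mg/kg q12h   15 mg/kg q24h
    3 mo to <12 yr            15 mg/kg q8h    10 mg/kg q12h   10 mg/kg q24h
    12 to <18 yr              15 mg/kg q8h    7.5 mg/kg q12h  7.5 mg/kg q24h
    ========================  ==============  ==============  ==============

    In the birth to <3 months group, subjects weighing <4 kg receive
    10 mg/kg instead of 15 (all renal categories).  Age groups are
    half-open: a patient exactly 2 years old is in "2 to <6 yr".
    """
    if not 0.0 <= age_years < 18.0:
        raise ValueError("age must be in [0, 18) years")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    category = renal_category_from_gfr_norm(gfr_norm)

    if age_years < 0.25:
        per_kg = 10.0 if weight_kg < LOW_WEIGHT_CUTOFF_KG else 15.0
        interval = 24.0 if category == "severe" else 12.0
        return Regimen(per_kg, interval)
    if age_years < 12.0:
        if category == "normal":
            return Regimen(15.0, 8.0)
        return Regimen(10.0, 12.0 if category == "moderate" else 24.0)
    if category == "normal":
        return Regimen(15.0, 8.0)
    return Regimen(7.5, 12.0 if category == "moderate" else 24.0)


# Study regimens: (age bands in years, mg/kg, infusion h); None interval = single dose.
_CSI_1006_BANDS = ((0.25, 2.0, 15.0), (2.0, 6.0, 15.0), (6.0, 12.0, 10.0), (12.0, 18.0, 7.0))
_BPR_PIP_002_BANDS = (
    (0.25, 2.0, 20.0, 4.0),
    (2.0, 6.0, 20.0, 2.0),
    (6.0, 12.0, 15.0, 2.0),
    (12.0, 18.0, 10.0, 2.0),
)


def study_regimen(study: str, age_years: float) -> Regimen:
    """The original regimen a study would have given a patient of this age.

    CSI-1006: single age-banded 2-h infusion (15/15/10/7 mg/kg by age band);
    BPR-PIP-001: single 7.5 mg/kg 4-h infusion in infants <3 months;
    BPR-PIP-002: q8h age-banded dosing (20/20/15/10 mg/kg; 4-h infusions
    under 2 years, 2-h otherwise).  Single-dose studies are encoded with a
    24-h interval and a 24-h simulation horizon yields exactly one dose.
    """
    if study == "CSI-1006":
        for lo, hi, per_kg in _CSI_1006_BANDS:
            if lo <= age_years < hi:
                return Regimen(per_kg, 24.0, 2.0)
        raise ValueError("CSI-1006 enrolled ages 3 months to <18 years")
    if study == "BPR-PIP-001":
        if 0.0 <= age_years < 0.25:
            return Regimen(7.5, 24.0, 4.0)
        raise ValueError("BPR-PIP-001 enrolled infants up to 3 months")
    if study == "BPR-PIP-002":
        for lo, hi, per_kg, dur in _BPR_PIP_002_BANDS:
            if lo <= age_years < hi:
                return Regimen(per_kg, 8.0, dur)
        raise ValueError("BPR-PIP-002 enrolled ages 3 months to <18 years")
    raise ValueError(f"unknown study {study!r}")


def expand_doses(r: Regimen, weight_kg: float, horizon_h: float = 24.0) -> list[DoseEvent]:
    """Concrete infusion events over [0, horizon): min(dose/kg·wt, cap) mg each."""
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    amount = min(r.dose_per_kg * weight_kg, r.cap)
    events = []
    t = 0.0
    while t < horizon_h:
        events.append(DoseEvent(start_time=t, amount=amount, duration=r.infusion_duration))
        t += r.interval
    return events


def policy_table() -> pd.DataFrame:
    """The optimized dosing policy as a human-readable table."""
    rows = []
    ages = [("birth to <3 mo", 0.1), ("3 mo to <2 yr", 1.0), ("2 to <6 yr", 4.0),
            ("6 to <12 yr", 9.0), ("12 to <18 yr", 15.0)]
    for label, age in ages:
        row = {"age_group": label}
        for cat, gfr in (("normal_or_mild", 100.0), ("moderate", 40.0), ("severe", 20.0)):
            r = optimized_regimen(age, 20.0, gfr)
            row[cat] = f"{r.dose_per_kg:g} mg/kg q{int(r.interval)}h"
        rows.append(row)
    return pd.DataFrame(rows)
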