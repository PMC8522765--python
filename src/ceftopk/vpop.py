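"""Virtual pediatric populations for Monte Carlo dosing simulations.

Generates hypothetical patients from birth to <18 years with uniform ages
within age groups, 50/50 sex, body size drawn from an embedded smoothed
growth reference (median and coefficient-of-variation curves for
weight-for-age and height-for-age, log-normal within age), and renal
function from the GFR maturation model — optionally replaced by a
renal-impairment category sampled on the BSA-normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariates as cov
from .covariates import IndividualEffects, PopulationModel, SubjectCovariates

__all__ = [
    "PopulationSpec",
    "GrowthReference",
    "VirtualSubject",
    "AGE_GROUPS",
    "age_group_label",
    "sample_population",
    "assign_gfr_normal",
    "impose_renal_impairment",
    "population_table",
]

#: The five simulation age groups, half-open [min, max) in years.
AGE_GROUPS: tuple[tuple[float, float], ...] = (
    (0.0, 0.25),
    (0.25, 2.0),
    (2.0, 6.0),
    (6.0, 12.0),
    (12.0, 18.0),
)

AGE_GROUP_LABELS = (
    "birth to <3 mo",
    "3 mo to <2 yr",
    "2 to <6 yr",
    "6 to <12 yr",
    "12 to <18 yr",
)

#: Default log-normal spread (CV) around the maturation-predicted GFR for
#: subjects with normal renal function.
GFR_POPULATION_CV = 0.15

_RENAL_BANDS = {"moderate": (30.0, 50.0), "severe": (10.0, 30.0)}

# Smoothed growth reference: age knots (years) with median weight (kg) and
# height (cm) per sex, log-linearly interpolated in age.  Values approximate
# the US CDC growth-chart 50th percentiles.
_AGE_KNOTS = np.array(
    [0.0, 1 / 12, 2 / 12, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0,
     12.0, 14.0, 16.0, 18.0]
)
_MEDIAN_WT = {
    "male": np.array(
        [3.53, 4.47, 5.57, 6.38, 7.93, 10.3, 12.7, 14.3, 16.3, 18.4, 20.7, 25.8,
         32.0, 40.5, 51.0, 60.5, 67.0]
    ),
    "female": np.array(
        [3.40, 4.20, 5.13, 5.85, 7.30, 9.5, 12.1, 13.9, 15.9, 18.0, 20.2, 25.5,
         33.0, 42.0, 49.5, 53.5, 56.5]
    ),
}
_MEDIAN_HT = {
    "male": np.array(
        [49.9, 54.7, 58.4, 61.4, 67.6, 75.7, 86.8, 95.3, 102.5, 109.0, 115.5,
         128.0, 138.5, 149.0, 164.0, 173.5, 176.5]
    ),
    "female": np.array(
        [49.3, 53.7, 57.1, 59.8, 65.9, 74.0, 85.5, 94.2, 101.6, 108.4, 115.0,
         127.5, 138.5, 151.5, 160.5, 162.5, 163.0]
    ),
}
# Log-scale SDs of weight and height within age (CV curves): weight spread
# grows from infancy into adolescence; height spread is narrow throughout.
_SD_LOG_WT = np.array(
    [0.13, 0.12, 0.12, 0.12, 0.12, 0.12, 0.12, 0.13, 0.14, 0.15, 0.16, 0.18,
     0.20, 0.21, 0.20, 0.19, 0.18]
)
_SD_LOG_HT = np.array(
    [0.035, 0.035, 0.035, 0.035, 0.035, 0.035, 0.038, 0.040, 0.040, 0.040,
     0.040, 0.042, 0.042, 0.045, 0.045, 0.038, 0.036]
)


@dataclass(frozen=True)
class GrowthReference:
    """Smoothed weight- and height-for-age reference with log-normal spread.

    ``median_weight``/``median_height`` interpolate the embedded median
    curves; a single z-score shared between weight and height per subject
    induces a weight–height correlation of 1.0 on the log scale, so
    simulated subjects are proportionate (heavier children are taller).
    """

    age_knots: np.ndarray = field(default_factory=lambda: _AGE_KNOTS)

    def median_weight(self, sex: str, age_years: float | np.ndarray) -> np.ndarray:
        return np.exp(np.interp(age_years, self.age_knots, np.log(_MEDIAN_WT[sex])))

    def median_height(self, sex: str, age_years: float | np.ndarray) -> np.ndarray:
        return np.exp(np.interp(age_years, self.age_knots, np.log(_MEDIAN_HT[sex])))

    def sd_log_weight(self, age_years: float | np.ndarray) -> np.ndarray:
        return np.interp(age_years, self.age_knots, _SD_LOG_WT)

    def sd_log_height(self, age_years: float | np.ndarray) -> np.ndarray:
        return np.interp(age_years, self.age_knots, _SD_LOG_HT)

    def sample_size(
        self, sex: str, age_years: float, z: float
    ) -> tuple[float, float]:
        """Weight (kg) and height (cm) at a shared size z-score."""
        wt = float(self.median_weight(sex, age_years) * np.exp(z * self.sd_log_weight(age_years)))
        ht = float(self.median_height(sex, age_years) * np.exp(z * self.sd_log_height(age_years)))
        return np.clip(wt, 2.0, 120.0), ht


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a simulated population.

    ``n_total`` subjects split equally (±1) across ``age_groups`` with ages
    uniform within each group; sex Bernoulli(``male_fraction``);
    ``renal_category`` of 'normal' keeps maturation-predicted GFR, while
    'moderate'/'severe' resample the BSA-normalized GFR within the
    impairment band.
    """

    n_total: int = 5000
    age_groups: tuple[tuple[float, float], ...] = AGE_GROUPS
    male_fraction: float = 0.5
    renal_category: str = "normal"
    seed: int = 0
    gfr_spread_cv: float = GFR_POPULATION_CV

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.renal_category not in ("normal", "moderate", "severe"):
            raise ValueError(f"unknown renal category {self.renal_category!r}")
        groups = sorted(self.age_groups)
        if groups[0][0] != 0.0 or any(
            a[1] != b[0] for a, b in zip(groups, groups[1:])
        ):
            raise ValueError("age groups must be non-overlapping and exhaustive from 0")


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated patient: covariates, age-group label and random effects."""

    subject_id: int
    group: str
    covariates: SubjectCovariates
    effects: IndividualEffects


def age_group_label(age_years: float) -> str:
    """Label of the simulation age group containing ``age_years`` (half-open)."""
    for (lo, hi), label in zip(AGE_GROUPS, AGE_GROUP_LABELS):
        if lo <= age_years < hi:
            return label
    raise ValueError(f"age {age_years} outside the supported range [0, 18)")


def assign_gfr_normal(
    sc: SubjectCovariates,
    rng: np.random.Generator | None = None,
    spread_cv: float = GFR_POPULATION_CV,
) -> float:
    """Absolute GFR (ml/min) assuming normal renal function for age and size.

    The maturation model is evaluated at the subject's PMA and FFM; a
    log-normal population spread with the given CV is applied when an ``rng``
    is supplied (``spread_cv=0`` or ``rng=None`` gives the deterministic
    curve).
    """
    gfr = cov.gfr_rhodin_ffm(sc.pma, sc.ffm)
    if rng is not None and spread_cv > 0:
        sd = np.sqrt(np.log1p(spread_cv**2))
        gfr *= float(np.exp(rng.normal(-sd * sd / 2.0, sd)))
    return gfr


def sample_population(
    spec: PopulationSpec,
    gr: GrowthReference | None = None,
    pm: PopulationModel | None = None,
) -> list[VirtualSubject]:
    """Draw a virtual pediatric population per the specification.

    Ages are uniform within each group with equal group counts (±1); sex is
    Bernoulli(male_fraction); weight and height come from the growth
    reference through a shared per-subject z-score; PMA = postnatal age +
    40 weeks (term gestation); FFM, BSA and GFR are filled by the covariate
    module, and GFR receives the normal-function log-normal spread.
    Individual η draws use the population model's ω² (zero if ``pm`` is
    omitted).  Fully reproducible from ``spec.seed``.
    """
    groups = sorted(spec.age_groups)
    if spec.n_total < len(groups):
        raise ValueError("n_total must be at least the number of age groups")
    gr = gr or GrowthReference()
    rng = np.random.default_rng(spec.seed)

    base, extra = divmod(spec.n_total, len(groups))
    counts = [base + (1 if i < extra else 0) for i in range(len(groups))]

    subjects: list[VirtualSubject] = []
    sid = 0
    for (lo, hi), n_g in zip(groups, counts):
        ages = rng.uniform(lo, hi, size=n_g)
        sexes = np.where(rng.random(n_g) < spec.male_fraction, "male", "female")
        zs = rng.normal(size=n_g)
        for age, sex, z in zip(ages, sexes, zs):
            wt, ht = gr.sample_size(str(sex), float(age), float(z))
            sc = SubjectCovariates(
                sex=str(sex),
                age_years=float(age),
                weight=wt,
                height=ht,
                gestational_age=40.0,
            )
            gfr = assign_gfr_normal(sc, rng, spread_cv=spec.gfr_spread_cv)
            sc = SubjectCovariates(
                sex=sc.sex,
                age_years=sc.age_years,
                weight=sc.weight,
                height=sc.height,
                gestational_age=40.0,
                pma=sc.pma,
                ffm=sc.ffm,
                bsa=sc.bsa,
                gfr=gfr,
                gfr_norm=gfr * 1.73 / sc.bsa,
            )
            if pm is not None:
                eff = IndividualEffects(
                    eta_cl=float(rng.normal(0.0, np.sqrt(pm.omega2_cl))),
                    eta_v1=float(rng.normal(0.0, np.sqrt(pm.omega2_v1))),
                )
            else:
                eff = IndividualEffects()
            subjects.append(
                VirtualSubject(
                    subject_id=sid,
                    group=age_group_label(float(age)),
                    covariates=sc,
                    effects=eff,
                )
            )
            sid += 1

    if spec.renal_category != "normal":
        subjects = impose_renal_impairment(subjects, spec.renal_category, rng)
    return subjects


def impose_renal_impairment(
    subjects: list[VirtualSubject],
    category: str,
    rng: np.random.Generator | int,
) -> list[VirtualSubject]:
    """Resample BSA-normalized GFR within a renal-impairment band.

    Moderate: 30 to <50 ml/min/1.73 m²; severe: 10 to <30 (the 10 floor
    avoids extrapolating toward the model's CL of zero at GFR zero).
    Absolute GFR is back-transformed through each subject's BSA.  Subjects
    whose normal-function gfr_norm is already below the band's upper edge
    keep the smaller of their own value and the sampled one, so "impairment"
    never improves renal function.
    """
    if category not in _RENAL_BANDS:
        raise ValueError(f"unknown renal category {category!r}")
    lo, hi = _RENAL_BANDS[category]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[VirtualSubject] = []
    for s in subjects:
        sc = s.covariates
        gfr_norm = float(rng.uniform(lo, hi))
        gfr_norm = max(min(gfr_norm, sc.gfr_norm), lo)
        gfr = gfr_norm * sc.bsa / 1.73
        sc2 = SubjectCovariates(
            sex=sc.sex,
            age_years=sc.age_years,
            weight=sc.weight,
            height=sc.height,
            gestational_age=sc.gestational_age,
            pma=sc.pma,
            ffm=sc.ffm,
            bsa=sc.bsa,
            gfr=gfr,
            gfr_norm=gfr_norm,
        )
        out.append(VirtualSubject(s.subject_id, s.group, sc2, s.effects))
    return out


def population_table(subjects: list[VirtualSubject]) -> pd.DataFrame:
    """Tidy one-row-per-subject table of a virtual population."""
    rows = []
    for s in subjects:
        sc = s.covariates
        rows.append(
            {
                "id": s.subject_id,
                "group": s.group,
                "sex": sc.sex,
                "age_years": sc.age_years,
                "pma_weeks": sc.pma,
                "weight_kg": sc.weight,
                "height_cm": sc.height,
                "ffm_kg": sc.ffm,
                "bsa_m2": sc.bsa,
                "gfr_ml_min": sc.gfr,
                "gfr_norm": sc.gfr_norm,
                "eta_cl": s.effects.eta_cl,
                "eta_v1": s.effects.eta_v1,
            }
        )
    return pd.DataFrame(rows)
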