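"""Synthetic sparse PK datasets that mirror the three pediatric study designs.

Generates design-faithful NONMEM-style long-format datasets (dose records
with EVID=1/MDV=1, observation records with EVID=0) with log-normal
interindividual variability, combined residual error, the studies' nominal
sampling schedules, and BLQ flagging — the statistical structure the
population analysis assumes.  Reading/writing round-trips through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from .covariates import IndividualEffects, PopulationModel, SubjectCovariates
from .pk3cmt import DoseEvent, simulate_profile
from .regimens import Regimen, study_regimen
from .vpop import GrowthReference, assign_gfr_normal

__all__ = [
    "StudyDesign",
    "DATASET_COLUMNS",
    "builtin_design",
    "simulate_study",
    "apply_exclusions",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "BLQ",
    "AGE", "WT", "HT", "SEX", "PMA", "GFR",
]

#: Assay lower limit of quantitation, μg/ml (configurable per design).
DEFAULT_LLOQ = 0.05


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule and enrollment window of one study (or age stratum).

    ``sampling_times`` are hours after the start of the *first* infusion of
    the sampling day; ``dosing_start`` shifts the nominal schedule to the
    sampling day for multi-dose designs (48 h = day 3 morning dose).
    """

    study_id: str
    age_range: tuple[float, float]  # years, half-open
    sampling_times: tuple[float, ...]  # h relative to sampling-day dose start
    dosing_start: float = 0.0  # h offset of the sampling-day dose
    multi_dose: bool = False
    lloq: float = DEFAULT_LLOQ
    #: overrides the built-in study dose rule (required for custom designs)
    regimen: "Regimen | None" = None

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.sampling_times):
            raise ValueError("sampling times must be nonnegative")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise ValueError("sampling times must be sorted")


_DESIGNS = {
    # single 2-h infusion; predose and 2, 3, 5, 8, 12, 24 h post start
    "CSI-1006": StudyDesign(
        "CSI-1006", (0.25, 18.0), (0.0, 2.0, 3.0, 5.0, 8.0, 12.0, 24.0)
    ),
    # term neonates; single 7.5 mg/kg 4-h infusion; predose and 2,4,6,8,12 h
    "BPR-PIP-001": StudyDesign(
        "BPR-PIP-001", (0.0, 0.25), (0.0, 2.0, 4.0, 6.0, 8.0, 12.0)
    ),
    # q8h multi-dose, day-3 sampling after the morning dose at 48 h:
    # >=2 y: predose, 2 (end of infusion), 4, 6, 8 h
    "BPR-PIP-002": StudyDesign(
        "BPR-PIP-002", (2.0, 18.0), (0.0, 2.0, 4.0, 6.0, 8.0),
        dosing_start=48.0, multi_dose=True,
    ),
    # <2 y stratum: predose, 4 (end of 4-h infusion), 6, 8 h
    "BPR-PIP-002-infant": StudyDesign(
        "BPR-PIP-002-infant", (0.25, 2.0), (0.0, 4.0, 6.0, 8.0),
        dosing_start=48.0, multi_dose=True,
    ),
}


def builtin_design(study_id: str) -> StudyDesign:
    """Return a built-in study design by id.

    Known ids: ``CSI-1006``, ``BPR-PIP-001``, ``BPR-PIP-002`` (ages ≥2 y)
    and ``BPR-PIP-002-infant`` (3 months to <2 years, 4-h infusions and a
    four-sample schedule).
    """
    try:
        return _DESIGNS[study_id]
    except KeyError:
        raise ValueError(
            f"unknown study {study_id!r}; known: {sorted(_DESIGNS)}"
        ) from None


def _draw_subject(
    design: StudyDesign, gr: GrowthReference, rng: np.random.Generator
) -> SubjectCovariates:
    lo, hi = design.age_range
    age = float(rng.uniform(lo, hi))
    sex = "male" if rng.random() < 0.5 else "female"
    wt, ht = gr.sample_size(sex, age, float(rng.normal()))
    sc = SubjectCovariates(sex=sex, age_years=age, weight=wt, height=ht)
    gfr = assign_gfr_normal(sc, rng)
    return SubjectCovariates(
        sex=sex, age_years=age, weight=wt, height=ht,
        pma=sc.pma, ffm=sc.ffm, bsa=sc.bsa, gfr=gfr,
        gfr_norm=gfr * 1.73 / sc.bsa,
    )


def simulate_study(
    design: StudyDesign,
    pm: PopulationModel,
    n: int,
    seed: int | np.random.Generator = 0,
    jitter_times: bool = False,
) -> pd.DataFrame:
    """Simulate a study replicate as a NONMEM-style long-format dataset.

    Subjects are drawn uniformly over the design's age range with
    growth-reference body size and normal-for-age renal function; individual
    parameters apply exp(η) IIV on CL and V1; observations carry combined
    proportional + additive residual error and are BLQ-flagged below the
    design's LLOQ.  ``jitter_times`` perturbs nominal sampling times by a
    uniform ±10% (nominal times by default).  Fully reproducible from seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gr = GrowthReference()
    study_key = design.study_id.replace("-infant", "")
    rows = []
    for sid in range(1, n + 1):
        sc = _draw_subject(design, gr, rng)
        if pm.omega2_cl > 0 or pm.omega2_v1 > 0:
            eff = cov.sample_effects(pm, 1, rng)[0]
        else:
            eff = IndividualEffects()
        ip = cov.individual_params(pm, sc, eff)
        regimen = design.regimen or study_regimen(study_key, sc.age_years)
        amount = min(regimen.dose_per_kg * sc.weight, regimen.cap)

        if design.multi_dose:
            dose_starts = np.arange(0.0, design.dosing_start + regimen.interval, regimen.interval)
            dose_starts = dose_starts[dose_starts <= design.dosing_start + 1e-9]
        else:
            dose_starts = np.array([design.dosing_start])
        doses = [
            DoseEvent(start_time=float(t), amount=amount, duration=regimen.infusion_duration)
            for t in dose_starts
        ]

        obs_times = np.asarray(design.sampling_times, dtype=float)
        if jitter_times:
            jit = 1.0 + rng.uniform(-0.1, 0.1, size=obs_times.size)
            obs_times = np.where(obs_times > 0, obs_times * jit, obs_times)
        obs_times = obs_times + design.dosing_start

        profile = simulate_profile(ip, doses, obs_times)
        dv = cov.apply_residual_error(profile.conc, pm, rng)
        # zero-noise pipeline stays exactly deterministic
        if pm.sigma2_prop == 0 and pm.sigma2_add == 0:
            dv = profile.conc.copy()

        covs = {
            "AGE": sc.age_years, "WT": sc.weight, "HT": sc.height,
            "SEX": 1 if sc.sex == "male" else 0, "PMA": sc.pma, "GFR": sc.gfr,
        }
        for d in doses:
            rows.append({
                "ID": sid, "TIME": d.start_time, "AMT": d.amount,
                "RATE": d.rate, "EVID": 1, "MDV": 1,
                "DV": np.nan, "BLQ": 0, **covs,
            })
        for t, y in zip(obs_times, dv):
            rows.append({
                "ID": sid, "TIME": float(t), "AMT": np.nan, "RATE": np.nan,
                "EVID": 0, "MDV": 0, "DV": float(y),
                "BLQ": int(y < design.lloq), **covs,
            })
    ds = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    # at equal clock times observations sort before dose records, so predose
    # samples precede the infusion they are drawn before
    ds = ds.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return ds


def apply_exclusions(
    ds: pd.DataFrame,
    screen_model: PopulationModel | None = None,
    residual_cutoff: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop unquantifiable observations; optionally screen gross outliers.

    BLQ observations and observations with missing DV are removed (the
    analysis-population convention: excluded, not imputed).  If a
    ``screen_model`` is given, observations whose standardized residual
    against the population-typical prediction exceeds ``residual_cutoff``
    in absolute value are also removed.  Returns the filtered dataset and
    counts by reason; record counts are conserved.
    """
    counts = {"blq": 0, "missing_dv": 0, "outlier": 0}
    obs = ds["EVID"] == 0
    blq_mask = obs & (ds["BLQ"] == 1)
    missing_mask = obs & ds["DV"].isna() & (ds["BLQ"] != 1)
    counts["blq"] = int(blq_mask.sum())
    counts["missing_dv"] = int(missing_mask.sum())
    keep = ~(blq_mask | missing_mask)
    out = ds[keep].copy()

    if screen_model is not None:
        drop_idx = []
        for sid, sub in out.groupby("ID"):
            obs_sub = sub[sub["EVID"] == 0]
            if obs_sub.empty:
                continue
            pred = _typical_predictions(screen_model, sub)
            sd = np.sqrt(
                screen_model.sigma2_prop * pred**2 + screen_model.sigma2_add
            )
            sd = np.maximum(sd, 1e-12)
            z = (obs_sub["DV"].to_numpy() - pred) / sd
            drop_idx.extend(obs_sub.index[np.abs(z) > residual_cutoff])
        counts["outlier"] = len(drop_idx)
        out = out.drop(index=drop_idx)
    return out.reset_index(drop=True), counts


def _typical_predictions(pm: PopulationModel, sub: pd.DataFrame) -> np.ndarray:
    """Population-typical predicted concentrations at a subject's observations."""
    first = sub.iloc[0]
    sc = SubjectCovariates(
        sex="male" if first["SEX"] == 1 else "female",
        age_years=float(first["AGE"]),
        weight=float(first["WT"]),
        height=float(first["HT"]),
        pma=float(first["PMA"]),
        gfr=float(first["GFR"]),
    )
    tp = cov.typical_params(pm, sc)
    dose_rows = sub[sub["EVID"] == 1]
    doses = [
        DoseEvent(float(r["TIME"]), float(r["AMT"]), float(r["AMT"] / r["RATE"]))
        for _, r in dose_rows.iterrows()
    ]
    obs_times = sub.loc[sub["EVID"] == 0, "TIME"].to_numpy(dtype=float)
    return simulate_profile(tp, doses, obs_times).conc


def validate_dataset(ds: pd.DataFrame) -> None:
    """Check dataset conventions; raise ``ValueError`` naming the first bad row.

    Dose records must have EVID=1, MDV=1 and no DV; observation records must
    have EVID=0 and no AMT; times must be nondecreasing within subject.
    """
    missing = [c for c in DATASET_COLUMNS if c not in ds.columns and c not in
               ("AGE", "WT", "HT", "SEX", "PMA", "GFR")]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    for i, row in ds.iterrows():
        if row["EVID"] == 1:
            if not np.isnan(row["DV"]):
                raise ValueError(f"row {i}: dose record (EVID=1) must not carry a DV")
            if np.isnan(row["AMT"]) or row["AMT"] <= 0:
                raise ValueError(f"row {i}: dose record must have a positive AMT")
        elif row["EVID"] == 0:
            if not np.isnan(row["AMT"]):
                raise ValueError(f"row {i}: observation record (EVID=0) must not carry AMT")
        else:
            raise ValueError(f"row {i}: unsupported EVID {row['EVID']}")
    for sid, sub in ds.groupby("ID"):
        t = sub["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"subject {sid}: times not nondecreasing")


def write_dataset(ds: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset to CSV after validating its conventions."""
    validate_dataset(ds)
    ds.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a NONMEM-style CSV dataset; extra columns survive."""
    ds = pd.read_csv(path)
    for col in ("ID", "EVID", "MDV", "BLQ"):
        if col in ds.columns:
            ds[col] = ds[col].astype(int)
    validate_dataset(ds)
    return ds
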