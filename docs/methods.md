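# Methods

This note records the model, the simulation conditions, the numerical
choices, and the known limits of what the tests demonstrate.

## Disposition model and its exact solution

Drug amounts in the central and two peripheral compartments follow a linear
system `da/dt = A a + b(t)`, where `A` is the 3×3 rate matrix built from the
micro constants (k10 = CL/V1, k12 = Q1/V1, k21 = Q1/Vp1, k13 = Q2/V1,
k31 = Q2/Vp2) and `b(t)` is the infusion rate into the central compartment,
piecewise constant. The simulator eigendecomposes `A` once per parameter set
and evaluates the closed form per dose: during an infusion of rate `R`
starting at 0, `a(t) = V diag((e^{λt}−1)/λ) V⁻¹ (R,0,0)ᵀ`; afterwards the
end-of-infusion state decays as `e^{λ(t−T)}`. Doses superpose (linear
kinetics). Mammillary models with positive parameters have three real,
distinct, negative eigenvalues; `(e^{λt}−1)/λ` switches to its series for
|λ| < 1e−12 so reduced (one/two-compartment) models evaluate cleanly. If two
eigenvalues agree to better than 1e−9 relative — a measure-zero parameter
set — the parameters are nudged by 1e−9 relative and a warning is emitted,
because the closed form is singular there. The analytic path agrees with an
adaptive ODE oracle (restarted at infusion boundaries) to better than 1e−6
relative on randomized configurations; the oracle lives only in the tests.

AUC is exact (piecewise closed form, `t1 = ∞` allowed) or trapezoidal on
the evaluation grid; the two differ by <0.5% on the 15-min grid. Cmax is
the grid maximum refined by a bounded scalar search of the analytic
solution inside the bracketing grid interval — for 2- and 4-h infusions it
sits at or just after the end of infusion.

## Covariate model

Fixed effects and variance components default to the final published
estimates (see the README table and `src/ceftopk/data/default_model.yaml`);
alternative models load from YAML. Choices the source left open:

* **Fat-free mass.** The maturation-adjusted pediatric FFM regression
  (weight–height–BMI hyperbola times a sex-specific age factor) anchors the
  adult reference at 56.1 kg for a 70 kg/176 cm man. Below 3 months the
  regression is unvalidated; a fixed fat-free fraction of 0.86·weight is
  used instead, which reproduces the neonate study's median GFR (5.85
  computed vs 5.90 reported ml/min at PMA 42 weeks).
* **BSA** is Mosteller's √(weight·height/3600) — the common pediatric
  default; it reproduces the studies' median BSA within ~6%.
* **Reference weight** 70 kg: the only value under which the published
  volume intercepts reproduce the reported weight-normalized steady-state
  volume (1.32 computed vs 1.33 reported L/kg at 3.98 kg).
* **%CV convention** for variance components is 100·√ω², which matches all
  printed conversions exactly, not the log-normal 100·√(exp(ω²)−1).
* The ω covariance is diagonal (no CL–V1 correlation was reported), and the
  additive residual σ² applies on the μg/ml concentration scale.

`MacroParams` requires CL > 0 (the kinetic layer's k10 > 0 invariant); the
covariate formula's property CL → 0 as GFR → 0 (nonrenal clearance fixed to
zero) is exercised in the limit rather than at the degenerate point.

## Virtual population

The Monte Carlo population mirrors the simulation design: five age groups
(birth–<3 mo, 3 mo–<2 y, 2–<6 y, 6–<12 y, 12–<18 y), ages uniform within
group with equal group counts, sex Bernoulli(0.5), PMA = postnatal age + 40
weeks (term gestation, matching the imputation evident in the source data).
Body size comes from an embedded smoothed growth reference — sex-specific
median weight/height-for-age knots approximating the US CDC 50th
percentiles, log-linearly interpolated, with age-dependent log-scale SDs
(weight CV ~12% in infancy rising to ~20% in adolescence; height CV ~4%).
One standard-normal z per subject drives both weight and height, so
simulated children are proportionate; the reference does not model
obesity/undernutrition tails or preterm strata, and PTA results should be
read accordingly.

Normal-for-age GFR is the maturation curve evaluated at the subject's PMA
and FFM times a mean-preserving log-normal spread with 15% CV
(`PopulationSpec.gfr_spread_cv`; 0 gives the deterministic curve). The
source specifies only "a standard equation that assumes normal renal
function"; the spread magnitude is therefore a documented knob, not an
estimate. Renal-impairment scenarios resample the BSA-normalized GFR
uniformly within the stated band (moderate 30–<50, severe 10–<30
ml/min/1.73 m², floor at 10), then back-transform to absolute GFR through
each subject's BSA; impairment never raises a healthy subject's GFR.

**Known limitation.** No reconstruction of the unspecified simulated-GFR
equation reproduces every published group simultaneously. The adopted
maturation curve is validated at the neonate study's median (within 1%) but
sits below the older studies' reported median GFR at mid-childhood
covariates (~50 vs 64.3 ml/min); consequently simulated mid-childhood
attainment runs slightly high, and the published neonate attainment at the
50%/60% thresholds (95.8/86.2) exceeds what this generator produces
(~89/~73) under any defensible spread setting. The 30%/40% threshold rows
and all deterministic checks agree. This is documented rather than tuned
away.

## Dosing and exposure

The optimized policy is total over age × weight × renal category: <3 mo →
15 mg/kg q12h (q24h if severe; 10 mg/kg whenever weight <4 kg), 3 mo–<12 y
→ 15 mg/kg q8h (10 mg/kg q12h moderate / q24h severe), 12–<18 y →
15 mg/kg q8h (7.5 mg/kg q12h / q24h); all 2-h infusions, every dose capped
at 500 mg, no rounding. Age bands are half-open (a child exactly 2 years
old is in 2–<6 y).

Exposure metrics are computed on day 1 only — the model implies modest
accumulation (q8h trough ratio ~1.2–1.3), and day-1 metrics are the
decision basis. %fT>MIC converts the MIC to the total-concentration scale
(4/0.84 ≈ 4.76 μg/ml) and locates threshold crossings by linear
interpolation between grid points, so refining the 15-min grid moves the
result by <0.5 percentage points. PTA simulations include the log-normal
IIV draw per subject. Comparison against adult steady-state exposure
requires the adult mean ± SD as explicit user input; there is no built-in
default.

## Synthetic trials and diagnostics

The trial generator reproduces each study's enrollment window, age-banded
doses, infusion durations and nominal sampling schedule (day-3 sampling
after the 48-h morning dose for the multi-dose study), with optional ±10%
uniform jitter of sampling times. LLOQ defaults to 0.05 μg/ml (the true
value is unpublished; only the exclusion mechanics matter). Predose samples
of single-dose designs are true zeros flagged BLQ. Exclusion handling drops
BLQ and missing observations (never imputes) and counts them by reason; an
optional screen drops observations with |standardized residual| > 3 against
a supplied model, a simplified stand-in for conditional-weighted-residual
screening.

MAP empirical-Bayes estimation minimizes the weighted residual sum of
squares with interaction weights (variance σ²p·f² + σ²a evaluated at the
current prediction) plus the prior η'Ω⁻¹η, by Nelder-Mead from η = 0 with
1e−8 objective tolerance. The Gaussian log-variance term is deliberately
omitted: with it, proportional error biases η away from zero even on exact
data; without it, noise-free data give η = 0 exactly, which is the contract
the diagnostics rely on. Zero ω² pins the corresponding η.

The PC-VPC corrects each observation by (bin-median population prediction)/
(own population prediction), bins at the distinct nominal times (sparse
bins merge into neighbors with a warning), and compares observed
5th/50th/95th percentiles to 90% bands from ≥100 simulated replicates. NPDE
is the rank of each observation among ≥500 simulated replicates mapped
through Φ⁻¹; the within-subject decorrelation step is omitted — defensible
at ≤7 samples/subject, but it can mildly inflate the normality statistic,
so NPDE here is a calibration instrument, not a publication-grade test.

Covariate-model recovery fits each subject's CL and V1 by iteratively
reweighted least squares (weights frozen between passes — letting the
variance model float inside the objective biases CL low by several
percent), holding the other parameters at population scaling. The CL–GFR
slope is exp(mean log(CLᵢ/GFRᵢ)) (median-unbiased under log-normal IIV);
the volume exponent is the log-log regression slope of V1 on weight/70;
ω²CL is the variance of log(CLᵢ/slope·GFRᵢ). At n = 200 subjects with the
full variance components the estimators are unbiased with per-replicate
sampling noise of ~2–4% (slope) and ~0.03–0.04 (exponent) — dominated by
the η draws themselves, not the estimation step.

## Problem sizes

Defaults chosen for the analyses shipped here: 1,000 virtual subjects per
age group for PTA (Monte Carlo SE ≤1.6 points at 50% attainment), 500
replicates for NPDE, 200 for VPC bands, 200 subjects × 12 samples × 10
seeds for recovery studies. All randomness flows through explicit seeds;
identical seeds give bit-identical outputs.
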