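"""Exact simulation of a three-compartment mammillary model with infusion input.

The model has a central compartment (volume ``v1``) exchanging drug with two
peripheral compartments, first-order elimination from the central compartment
(clearance ``cl``), and zero-order (constant-rate infusion) input.  Amounts are
in mg, volumes in liters and times in hours, so central concentration
``amount / v1`` is directly in μg/ml.

The solution is the analytic piecewise closed form obtained by
eigendecomposition of the 3×3 first-order rate matrix, evaluated segment by
segment over infusion on/off windows and superposed over doses.  An adaptive
ODE integrator is deliberately *not* used on the main path; it serves only as
an independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MacroParams",
    "MicroRates",
    "DoseEvent",
    "ConcentrationProfile",
    "to_micro",
    "rate_matrix",
    "simulate_profile",
    "auc",
    "vss",
    "phase_half_lives",
    "cmax",
]

# Relative eigenvalue separation below which the closed form is numerically
# singular; parameters are then nudged by the same relative amount.
_EIG_DEGENERACY_RTOL = 1e-9


class InvalidParameterError(ValueError):
    """Raised when pharmacokinetic parameters violate their physical domain."""


@dataclass(frozen=True)
class MacroParams:
    """Macro-constant parameterization of the three-compartment model.

    Parameters
    ----------
    cl : float
        Elimination clearance from the central compartment, liters/h.
    v1 : float
        Central volume of distribution, liters.
    q1, vp1 : float
        Distributional clearance (liters/h) and volume (liters) of the
        first (shallow) peripheral compartment.
    q2, vp2 : float
        Distributional clearance and volume of the second peripheral
        compartment.

    ``q1`` / ``q2`` may be zero for deliberately reduced (one- or
    two-compartment) models; the corresponding peripheral volume is then
    inert.
    """

    cl: float
    v1: float
    q1: float
    vp1: float
    q2: float
    vp2: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0):
            raise InvalidParameterError("cl and v1 must be strictly positive")
        if self.q1 < 0 or self.q2 < 0:
            raise InvalidParameterError("distributional clearances must be >= 0")
        if self.vp1 <= 0 and self.q1 > 0:
            raise InvalidParameterError("vp1 must be positive when q1 > 0")
        if self.vp2 <= 0 and self.q2 > 0:
            raise InvalidParameterError("vp2 must be positive when q2 > 0")


@dataclass(frozen=True)
class MicroRates:
    """First-order micro rate constants (1/h) of the mammillary model."""

    k10: float
    k12: float
    k21: float
    k13: float
    k31: float


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion.

    ``start_time`` is hours since time origin, ``amount`` mg, ``duration``
    hours.  Bolus doses are represented by a short but nonzero duration.
    """

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidParameterError("dose amount must be positive")
        if self.duration <= 0:
            raise InvalidParameterError("infusion duration must be positive")
        if self.start_time < 0:
            raise InvalidParameterError("dose start time must be >= 0")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class ConcentrationProfile:
    """Total plasma concentration (μg/ml) on a strictly increasing time grid."""

    times: np.ndarray
    conc: np.ndarray
    params: MacroParams | None = field(default=None, compare=False)
    doses: tuple[DoseEvent, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and conc must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)


def to_micro(p: MacroParams) -> MicroRates:
    """Convert macro constants to micro rate constants.

    k10 = cl/v1, k12 = q1/v1, k21 = q1/vp1, k13 = q2/v1, k31 = q2/vp2.
    A zero distributional clearance yields zero exchange rates for that
    peripheral compartment.
    """
    return MicroRates(
        k10=p.cl / p.v1,
        k12=p.q1 / p.v1,
        k21=p.q1 / p.vp1 if p.q1 > 0 else 0.0,
        k13=p.q2 / p.v1,
        k31=p.q2 / p.vp2 if p.q2 > 0 else 0.0,
    )


def rate_matrix(p: MacroParams) -> np.ndarray:
    """3×3 first-order rate matrix acting on compartment amounts (mg)."""
    k = to_micro(p)
    return np.array(
        [
            [-(k.k10 + k.k12 + k.k13), k.k21, k.k31],
            [k.k12, -k.k21, 0.0],
            [k.k13, 0.0, -k.k31],
        ]
    )


def _eigensystem(p: MacroParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the rate matrix with a degeneracy guard.

    Mammillary models with positive parameters have three real, distinct,
    nonpositive eigenvalues.  At (measure-zero) parameter sets where two
    eigenvalues coincide to within ``_EIG_DEGENERACY_RTOL`` the closed form
    is singular; parameters are nudged by the same relative amount and a
    warning is emitted.
    """
    a = rate_matrix(p)
    lam, vec = np.linalg.eig(a)
    lam = np.real(lam)
    vec = np.real(vec)
    scale = max(np.max(np.abs(lam)), 1e-300)
    srt = np.sort(lam)
    if np.any(np.abs(np.diff(srt)) < _EIG_DEGENERACY_RTOL * scale):
        warnings.warn(
            "near-degenerate eigenvalues; perturbing parameters by 1e-9 relative",
            RuntimeWarning,
            stacklevel=3,
        )
        bump = 1.0 + 1e-9
        p2 = MacroParams(p.cl * bump, p.v1, p.q1, p.vp1 * bump, p.q2, p.vp2 / bump)
        a = rate_matrix(p2)
        lam, vec = np.linalg.eig(a)
        lam, vec = np.real(lam), np.real(vec)
    vinv = np.linalg.inv(vec)
    return lam, vec, vinv


def _phi(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(exp(lam*t) - 1)/lam elementwise, with the t limit as lam -> 0.

    Shapes: lam (3,), t (...,) -> output (..., 3).
    """
    t = np.asarray(t, dtype=float)[..., None]
    out = np.empty(np.broadcast_shapes(t.shape, (1, 3))[:-1] + (3,))
    small = np.abs(lam) < 1e-12
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(small, t * (1.0 + lam * t / 2.0), np.expm1(lam * t) / np.where(small, 1.0, lam))
    return out


def _single_dose_amounts(
    lam: np.ndarray, vec: np.ndarray, vinv: np.ndarray, dose: DoseEvent, times: np.ndarray
) -> np.ndarray:
    """Compartment amounts (mg) from one infusion at the requested times.

    Returns array of shape (len(times), 3); zero before the dose starts.
    """
    tau = np.asarray(times, dtype=float) - dose.start_time
    w = vinv[:, 0] * dose.rate  # V^{-1} @ (rate, 0, 0)
    amounts = np.zeros((tau.size, 3))

    during = (tau > 0) & (tau <= dose.duration)
    after = tau > dose.duration
    if np.any(during):
        g = _phi(lam, tau[during])  # (n, 3)
        amounts[during] = (g * w) @ vec.T
    if np.any(after):
        g_end = _phi(lam, np.array(dose.duration))  # (3,)
        decay = np.exp(np.outer(tau[after] - dose.duration, lam))
        amounts[after] = (decay * g_end * w) @ vec.T
    return amounts


def simulate_amounts(
    p: MacroParams, doses: list[DoseEvent] | tuple[DoseEvent, ...], times: np.ndarray
) -> np.ndarray:
    """Amounts (mg) in the three compartments over ``times``, all doses superposed."""
    lam, vec, vinv = _eigensystem(p)
    times = np.asarray(times, dtype=float)
    total = np.zeros((times.size, 3))
    for d in doses:
        total += _single_dose_amounts(lam, vec, vinv, d, times)
    return total


def simulate_profile(
    p: MacroParams, doses: list[DoseEvent] | tuple[DoseEvent, ...], times: np.ndarray
) -> ConcentrationProfile:
    """Central-compartment concentration profile, exact to machine precision.

    ``doses`` need not be sorted; superposition makes order irrelevant for
    linear kinetics.  Concentration is continuous across infusion-stop
    boundaries by construction.
    """
    amounts = simulate_amounts(p, doses, times)
    conc = np.clip(amounts[:, 0] / p.v1, 0.0, None)
    return ConcentrationProfile(
        times=np.asarray(times, dtype=float), conc=conc, params=p, doses=tuple(doses)
    )


def _analytic_auc(
    p: MacroParams, doses: tuple[DoseEvent, ...], t0: float, t1: float
) -> float:
    """Exact integral of central concentration over [t0, t1]; t1 may be inf."""
    lam, vec, vinv = _eigensystem(p)
    total = 0.0
    for d in doses:
        w = vinv[:, 0] * d.rate
        c = vec[0, :] * w  # amounts a1(t) = sum_j c_j * g_j(t - start)
        a = max(t0 - d.start_time, 0.0)
        b = t1 - d.start_time
        if b <= 0:
            continue
        # integral of g_j over [a, b] where g_j(t) = (e^{lam t}-1)/lam during
        # infusion and e^{lam (t-T)} g_j(T) after
        T = d.duration
        seg = 0.0
        for cj, lj in zip(c, lam):
            if abs(lj) < 1e-12:
                continue  # inert direction (zero eigenvalue, zero weight)
            # during-infusion part over [a, min(b, T)]
            lo, hi = a, min(b, T)
            if hi > lo:
                seg += cj * ((np.expm1(lj * hi) - np.expm1(lj * lo)) / lj - (hi - lo)) / lj
            # post-infusion part over [max(a, T), b]
            lo = max(a, T)
            if b > lo:
                g_end = np.expm1(lj * T) / lj
                if np.isinf(b):
                    seg += cj * g_end * (-np.exp(lj * (lo - T)) / lj)
                else:
                    seg += cj * g_end * (np.exp(lj * (b - T)) - np.exp(lj * (lo - T))) / lj
        total += seg
    return total / p.v1


def auc(
    profile: ConcentrationProfile,
    t0: float = 0.0,
    t1: float = 24.0,
    method: str = "trapezoid",
) -> float:
    """Area under the concentration curve over [t0, t1], μg·h/ml.

    ``method='trapezoid'`` integrates the stored grid linearly (the grid must
    cover [t0, t1]); ``method='analytic'`` integrates the piecewise closed
    form exactly and accepts ``t1 = inf``, provided the profile retains its
    generating parameters and doses.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if method == "analytic":
        if profile.params is None or profile.doses is None:
            raise ValueError("analytic AUC requires a model-generated profile")
        return _analytic_auc(profile.params, profile.doses, t0, t1)
    if method != "trapezoid":
        raise ValueError(f"unknown method {method!r}")
    t, c = profile.times, profile.conc
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("trapezoid AUC window outside the simulated span")
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    return float(np.trapezoid(c[mask], t[mask]))


def vss(p: MacroParams) -> float:
    """Steady-state volume of distribution: v1 + vp1 + vp2, liters.

    Peripheral volumes with zero distributional clearance do not contribute.
    """
    total = p.v1
    if p.q1 > 0:
        total += p.vp1
    if p.q2 > 0:
        total += p.vp2
    return total


def phase_half_lives(p: MacroParams) -> np.ndarray:
    """Half-lives (h) of the disposition phases, shortest first.

    These are −ln 2 / λ for the negative eigenvalues of the rate matrix.
    Degenerate models with zero distributional clearance have fewer phases;
    only the defined (finite, positive) half-lives are returned.
    """
    lam = np.linalg.eigvals(rate_matrix(p))
    lam = np.real(lam)
    lam = lam[lam < -1e-12]
    return np.sort(np.log(2.0) / -lam)


def cmax(profile: ConcentrationProfile, refine: bool = True) -> tuple[float, float]:
    """Maximum concentration and its time over the profile's grid.

    With ``refine=True`` and a model-generated profile, the grid maximum is
    polished by a golden-section search of the analytic solution within the
    bracketing grid interval.  Returns ``(cmax, tmax)``.
    """
    i = int(np.argmax(profile.conc))
    best_c, best_t = float(profile.conc[i]), float(profile.times[i])
    if not refine or profile.params is None or profile.doses is None:
        return best_c, best_t
    lo = profile.times[max(i - 1, 0)]
    hi = profile.times[min(i + 1, profile.times.size - 1)]
    if hi <= lo:
        return best_c, best_t
    from scipy.optimize import minimize_scalar

    p, doses = profile.params, profile.doses

    def neg_conc(t: float) -> float:
        return -simulate_amounts(p, doses, np.array([t]))[0, 0] / p.v1

    res = minimize_scalar(neg_conc, bounds=(lo, hi), method="bounded")
    if -res.fun > best_c:
        best_c, best_t = float(-res.fun), float(res.x)
    return best_c, best_t
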