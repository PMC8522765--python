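import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ceftopk import covariates as cov
from ceftopk import pk3cmt


@pytest.fixture(scope="session")
def pm():
    """The shipped final population model."""
    return cov.load_model()


@pytest.fixture(scope="session")
def neonate_sc():
    """Study-median term neonate: weight 3.98 kg, PMA 42 wk, GFR 5.90 ml/min."""
    return cov.SubjectCovariates(
        sex="male", age_years=0.022, weight=3.98, height=54.0, pma=42.0, gfr=5.90
    )


@pytest.fixture(scope="session")
def neonate_typical(pm, neonate_sc):
    """Population-typical parameters at the neonate study's median covariates."""
    return cov.typical_params(pm, neonate_sc)


def ode_profile(p: pk3cmt.MacroParams, doses, times, rtol=1e-11) -> np.ndarray:
    """Independent adaptive-ODE oracle for the three-compartment infusion model.

    Integrates the amount system with scipy's solve_ivp, restarting at every
    infusion on/off boundary so the discontinuous input is handled exactly.
    """
    k = pk3cmt.to_micro(p)

    def rhs_factory(rate):
        def rhs(t, a):
            return [
                rate - (k.k10 + k.k12 + k.k13) * a[0] + k.k21 * a[1] + k.k31 * a[2],
                k.k12 * a[0] - k.k21 * a[1],
                k.k13 * a[0] - k.k31 * a[2],
            ]

        return rhs

    times = np.asarray(times, dtype=float)
    breaks = sorted(
        {0.0, times[-1]}
        | {d.start_time for d in doses}
        | {d.start_time + d.duration for d in doses}
    )
    breaks = [b for b in breaks if b <= times[-1]]
    if breaks[-1] < times[-1]:
        breaks.append(times[-1])
    state = np.zeros(3)
    conc = np.full(times.size, np.nan)
    if times[0] == 0.0:
        conc[0] = 0.0
    for a, b in zip(breaks, breaks[1:]):
        rate = sum(d.rate for d in doses if d.start_time <= a < d.start_time + d.duration)
        t_eval = times[(times > a) & (times <= b)]
        sol = solve_ivp(
            rhs_factory(rate), (a, b), state,
            t_eval=np.concatenate([t_eval, [b]]) if (t_eval.size == 0 or t_eval[-1] < b) else t_eval,
            rtol=rtol, atol=1e-14, max_step=(b - a) / 4,
        )
        for t, y in zip(sol.t, sol.y[0]):
            idx = np.nonzero(np.isclose(times, t, atol=1e-12))[0]
            if idx.size:
                conc[idx[0]] = y / p.v1
        state = sol.y[:, -1]
    assert not np.any(np.isnan(conc))
    return conc


def random_macro_params(rng: np.random.Generator) -> pk3cmt.MacroParams:
    """A random positive parameter set spanning neonatal to adult magnitudes."""
    return pk3cmt.MacroParams(
        cl=float(rng.uniform(0.05, 10.0)),
        v1=float(rng.uniform(0.5, 30.0)),
        q1=float(rng.uniform(0.01, 5.0)),
        vp1=float(rng.uniform(0.5, 80.0)),
        q2=float(rng.uniform(0.01, 5.0)),
        vp2=float(rng.uniform(0.2, 20.0)),
    )
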