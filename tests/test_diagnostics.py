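"""Qualification diagnostics: MAP estimation, PC-VPC, NPDE, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from ceftopk import covariates as cov
from ceftopk import diagnostics as dx
from ceftopk import trialsim as ts


def rich_design(age_range=(0.0, 18.0)):
    """Dense single-dose sampling over the full pediatric range (synthetic).

    Early samples during and just after the 2-h infusion identify the
    central volume; later samples carry clearance information.
    """
    from ceftopk.regimens import Regimen

    times = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0)
    return ts.StudyDesign(
        "rich-synthetic", age_range, times, lloq=1e-6,
        regimen=Regimen(15.0, 24.0, 2.0),
    )


@pytest.fixture(scope="module")
def tiny_noise_pm():
    return cov.PopulationModel(sigma2_prop=1e-6, sigma2_add=1e-8)


def make_subject_ds(pm, eta, times, noise_seed, weight=18.0, height=108.0, age=5.0):
    """One-subject dataset: 15 mg/kg 2-h infusion, observations at ``times``.

    ``noise_seed=None`` produces noise-free observations.
    """
    from ceftopk.pk3cmt import DoseEvent, simulate_profile

    sc = cov.SubjectCovariates(sex="male", age_years=age, weight=weight, height=height)
    ip = cov.individual_params(pm, sc, eta)
    dose = DoseEvent(0.0, 15.0 * weight, 2.0)
    conc = simulate_profile(ip, [dose], times).conc
    if noise_seed is not None:
        conc = cov.apply_residual_error(conc, pm, noise_seed)
    covs = {"AGE": age, "WT": weight, "HT": height, "SEX": 1, "PMA": sc.pma, "GFR": sc.gfr}
    rows = [{"ID": 1, "TIME": 0.0, "AMT": dose.amount, "RATE": dose.rate,
             "EVID": 1, "MDV": 1, "DV": np.nan, "BLQ": 0, **covs}]
    for t, y in zip(times, conc):
        rows.append({"ID": 1, "TIME": float(t), "AMT": np.nan, "RATE": np.nan,
                     "EVID": 0, "MDV": 0, "DV": float(y), "BLQ": 0, **covs})
    return pd.DataFrame(rows, columns=ts.DATASET_COLUMNS)


class TestMapEstimate:
    def test_zero_noise_data_gives_zero_etas(self, pm):
        gen = cov.PopulationModel(
            omega2_cl=0.0, omega2_v1=0.0, sigma2_prop=0.0, sigma2_add=0.0
        )
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), gen, n=3, seed=0)
        for _, sub in ds.groupby("ID"):
            ebe = dx.map_estimate(pm, sub)
            assert abs(ebe.eta_cl) < 1e-4
            assert abs(ebe.eta_v1) < 1e-4

    def test_known_eta_recovered_from_rich_data(self, tiny_noise_pm):
        # subject simulated at eta_cl = ln 1.5 with negligible noise: the
        # likelihood dominates the prior and the eta is recovered within 1%
        true_eta = np.log(1.5)
        sub = make_subject_ds(
            tiny_noise_pm, eta=cov.IndividualEffects(true_eta, 0.0),
            times=np.linspace(0.5, 23.0, 12), noise_seed=None,
        )
        ebe = dx.map_estimate(tiny_noise_pm, sub)
        assert ebe.eta_cl == pytest.approx(true_eta, rel=0.01)

    def test_sparse_data_shrinks_toward_zero(self, pm):
        # one sample per subject: posterior modes shrink below the true etas
        rng = np.random.default_rng(17)
        abs_true, abs_est = [], []
        for _ in range(40):
            eta = cov.IndividualEffects(
                float(rng.normal(0, np.sqrt(pm.omega2_cl))),
                float(rng.normal(0, np.sqrt(pm.omega2_v1))),
            )
            sub = make_subject_ds(
                pm, eta=eta, times=np.array([3.0]),
                noise_seed=int(rng.integers(1 << 30)),
            )
            ebe = dx.map_estimate(pm, sub)
            abs_true.append(abs(eta.eta_cl))
            abs_est.append(abs(ebe.eta_cl))
        assert np.mean(abs_est) < np.mean(abs_true)

    def test_no_observations_rejected(self, pm):
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), pm, n=1, seed=0)
        doses_only = ds[ds["EVID"] == 1]
        with pytest.raises(ValueError):
            dx.map_estimate(pm, doses_only)


class TestNPDE:
    def test_extreme_observation_hits_extreme_npde(self, pm):
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), pm, n=2, seed=1)
        obs_idx = ds[(ds["EVID"] == 0) & (ds["BLQ"] == 0)].index
        ds.loc[obs_idx[0], "DV"] = 1e6
        res = dx.npde(ds, pm, n_sim=500, seed=0)
        from scipy.stats import norm

        assert res.npde.max() == pytest.approx(norm.ppf((500 + 0.5) / 501), rel=1e-9)

    def test_halved_clearance_model_biases_npde_negative(self, pm):
        # data generated under pm, evaluated under a model with half the slope:
        # that model predicts too-high concentrations, so observed ranks low
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), pm, n=25, seed=21)
        wrong = cov.PopulationModel(cl_gfr_slope=pm.cl_gfr_slope / 2)
        res = dx.npde(ds, wrong, n_sim=500, seed=3)
        n_obs = np.sum(np.isfinite(res.npde))
        z = res.mean / (1.0 / np.sqrt(n_obs))
        assert z < -3.0


class TestPCVPC:
    def test_identical_subjects_make_correction_identity(self, pm):
        # one covariate vector repeated: population prediction constant per bin
        gen = cov.PopulationModel(omega2_cl=0.0, omega2_v1=0.0,
                                  sigma2_prop=0.0, sigma2_add=0.0)
        base = ts.simulate_study(ts.builtin_design("CSI-1006"), gen, n=1, seed=8)
        reps = []
        for i in range(6):
            r = base.copy()
            r["ID"] = i + 1
            reps.append(r)
        ds = pd.concat(reps, ignore_index=True)
        res = dx.pc_vpc(ds, pm, n_sim=100, seed=0)
        obs = ds[(ds["EVID"] == 0) & (ds["BLQ"] == 0)]
        med_by_time = obs.groupby("TIME")["DV"].median()
        for _, row in res.table.iterrows():
            assert row["obs_p50"] == pytest.approx(med_by_time.loc[row["bin_time"]], rel=1e-9)

    def test_doubled_observations_shift_observed_not_simulated(self, pm):
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), pm, n=20, seed=30)
        res1 = dx.pc_vpc(ds, pm, n_sim=100, seed=5)
        ds2 = ds.copy()
        obs = ds2["EVID"] == 0
        ds2.loc[obs, "DV"] *= 2
        res2 = dx.pc_vpc(ds2, pm, n_sim=100, seed=5)
        np.testing.assert_allclose(
            res2.table["obs_p50"], 2 * res1.table["obs_p50"], rtol=1e-9
        )
        np.testing.assert_allclose(
            res2.table["sim_p50_lo"], res1.table["sim_p50_lo"], rtol=1e-9
        )

    def test_min_nsim_enforced(self, pm):
        ds = ts.simulate_study(ts.builtin_design("CSI-1006"), pm, n=3, seed=0)
        with pytest.raises(ValueError):
            dx.pc_vpc(ds, pm, n_sim=50)


class TestRecovery:
    def test_noise_free_recovery_is_consistent(self, pm, tiny_noise_pm):
        gen = cov.PopulationModel(
            omega2_cl=0.0, omega2_v1=0.0,
            sigma2_prop=tiny_noise_pm.sigma2_prop, sigma2_add=tiny_noise_pm.sigma2_add,
        )
        ds = ts.simulate_study(rich_design(), gen, n=100, seed=13)
        rep = dx.recover_covariate_model(ds, gen)
        assert abs(rep.rel_error_slope) < 0.01
        assert abs(rep.vol_exponent - gen.vol_exponent) < 0.02
        assert rep.omega2_cl < 0.005  # no-IIV limit

    def test_full_noise_recovery_single_seed(self, pm):
        ds = ts.simulate_study(rich_design(), pm, n=100, seed=41)
        rep = dx.recover_covariate_model(ds, pm)
        assert abs(rep.rel_error_slope) < 0.10
        assert abs(rep.vol_exponent - pm.vol_exponent) < 0.10
        assert rep.omega2_cl == pytest.approx(pm.omega2_cl, abs=0.03)
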