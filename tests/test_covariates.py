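"""Covariate model: body-size physiology, GFR maturation, IIV and residual error."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ceftopk as cp
from ceftopk import covariates as cov


class TestFatFreeMass:
    def test_standard_adult_male_anchors_reference(self):
        assert cov.fat_free_mass("male", 70.0, 176.0, 35.0) == pytest.approx(56.1, rel=0.005)

    def test_infant_fixed_fraction(self):
        assert cov.fat_free_mass("male", 3.98, 54.0, 0.02) == pytest.approx(0.86 * 3.98)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        sex=st.sampled_from(["male", "female"]),
        weight=st.floats(2.5, 120.0),
        height=st.floats(45.0, 200.0),
        age=st.floats(0.0, 18.0),
    )
    def test_never_exceeds_body_weight(self, sex, weight, height, age):
        ffm = cov.fat_free_mass(sex, weight, height, age)
        assert 0 < ffm <= weight

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(Exception):
            cov.fat_free_mass("male", -1.0, 170.0, 10.0)


class TestBodySurfaceArea:
    @pytest.mark.parametrize(
        "wt,ht,expected", [(70.0, 170.0, 1.818), (3.98, 54.0, 0.2443)]
    )
    def test_mosteller_values(self, wt, ht, expected):
        assert cov.body_surface_area(wt, ht) == pytest.approx(expected, rel=1e-3)

    def test_quadrupling_product_doubles_bsa(self):
        assert cov.body_surface_area(40.0, 160.0) == pytest.approx(
            2 * cov.body_surface_area(20.0, 80.0)
        )


class TestGFRMaturation:
    def test_half_maturation_identity_exact(self):
        rp = cov.RhodinParams()
        assert cov.gfr_rhodin_ffm(rp.tm50, rp.ffm_ref, rp) == pytest.approx(
            rp.gfr_std / 2, rel=1e-12
        )

    def test_adult_asymptote(self):
        assert cov.gfr_rhodin_ffm(1e6, 56.1) == pytest.approx(121.2, rel=1e-6)

    def test_term_neonate_matches_study_median(self):
        # PMA 42 wk, FFM 0.86*3.98 kg -> 5.85; printed study median 5.90 (within 2%)
        gfr = cov.gfr_rhodin_ffm(42.0, 0.86 * 3.98)
        assert gfr == pytest.approx(5.85, abs=0.01)
        assert abs(gfr - 5.90) / 5.90 < 0.02

    def test_monotone_in_pma_and_ffm(self):
        base = cov.gfr_rhodin_ffm(45.0, 10.0)
        assert cov.gfr_rhodin_ffm(46.0, 10.0) > base
        assert cov.gfr_rhodin_ffm(45.0, 11.0) > base


class TestTypicalParams:
    def test_neonate_macro_values(self, neonate_typical):
        tp = neonate_typical
        assert tp.cl == pytest.approx(0.3233, rel=1e-3)
        assert tp.v1 == pytest.approx(1.182, rel=1e-3)
        assert tp.vp1 == pytest.approx(3.633, rel=1e-3)
        assert tp.q1 == pytest.approx(0.0635, rel=2e-3)
        assert tp.q2 == pytest.approx(0.4027, rel=1e-3)
        assert cp.vss(tp) / 3.98 == pytest.approx(1.3226, rel=1e-3)

    def test_reference_weight_identity(self, pm):
        sc = cov.SubjectCovariates(sex="male", age_years=35.0, weight=70.0, height=176.0)
        tp = cov.typical_params(pm, sc)
        assert tp.v1 == pytest.approx(pm.v1_ref, rel=1e-12)
        assert tp.vp1 == pytest.approx(pm.vp1_ref, rel=1e-12)
        assert tp.vp2 == pytest.approx(pm.vp2_ref, rel=1e-12)
        assert tp.q1 == pytest.approx(pm.q1_ref, rel=1e-12)
        assert tp.q2 == pytest.approx(pm.q2_ref, rel=1e-12)

    def test_clearance_proportional_to_gfr_with_zero_nonrenal(self, pm):
        # CL_NR is fixed to zero, so CL -> 0 linearly as GFR -> 0
        sc_lo = cov.SubjectCovariates(
            sex="male", age_years=1.0, weight=10.0, height=75.0, gfr=1e-6
        )
        assert cov.typical_params(pm, sc_lo).cl == pytest.approx(pm.cl_gfr_slope * 1e-6)
        assert pm.cl_nr == 0.0

    def test_monotone_in_gfr_and_weight(self, pm):
        mk = lambda gfr, wt: cov.typical_params(
            pm, cov.SubjectCovariates(sex="male", age_years=5.0, weight=wt, height=110.0, gfr=gfr)
        )
        assert mk(60.0, 20.0).cl > mk(50.0, 20.0).cl
        a, b = mk(50.0, 25.0), mk(50.0, 20.0)
        assert a.v1 > b.v1 and a.vp1 > b.vp1 and a.vp2 > b.vp2
        assert a.q1 > b.q1 and a.q2 > b.q2


class TestIndividualVariability:
    def test_zero_etas_equal_typical(self, pm, neonate_sc, neonate_typical):
        ip = cov.individual_params(pm, neonate_sc, cov.IndividualEffects(0.0, 0.0))
        assert ip == neonate_typical

    def test_eta_cl_scales_clearance_only(self, pm, neonate_sc, neonate_typical):
        ip = cov.individual_params(pm, neonate_sc, cov.IndividualEffects(math.log(2), 0.0))
        assert ip.cl == pytest.approx(2 * neonate_typical.cl)
        assert ip.v1 == pytest.approx(neonate_typical.v1)

    def test_lognormal_moment_identity(self, pm):
        effs = cov.sample_effects(pm, 100_000, np.random.default_rng(2024))
        mean_exp = np.mean([math.exp(e.eta_cl) for e in effs])
        assert mean_exp == pytest.approx(math.exp(pm.omega2_cl / 2), rel=0.01)

    def test_sample_effects_reproducible_and_calibrated(self, pm):
        a = cov.sample_effects(pm, 1000, 42)
        b = cov.sample_effects(pm, 1000, 42)
        assert a == b
        big = cov.sample_effects(pm, 100_000, 7)
        var = np.var([e.eta_cl for e in big])
        assert var == pytest.approx(pm.omega2_cl, rel=0.03)

    def test_zero_variance_gives_zero_etas(self):
        pm0 = cov.PopulationModel(omega2_cl=0.0, omega2_v1=0.0)
        effs = cov.sample_effects(pm0, 10, 0)
        assert all(e.eta_cl == 0.0 and e.eta_v1 == 0.0 for e in effs)


class TestResidualError:
    def test_zero_noise_is_identity(self):
        pm0 = cov.PopulationModel(sigma2_prop=0.0, sigma2_add=0.0)
        pred = np.array([0.0, 1.0, 10.0])
        np.testing.assert_array_equal(cov.apply_residual_error(pred, pm0, 0), pred)

    def test_combined_error_sd_at_pred_10(self, pm):
        y = cov.apply_residual_error(np.full(100_000, 10.0), pm, 11)
        expected_sd = math.sqrt(100 * pm.sigma2_prop + pm.sigma2_add)
        assert np.std(y) == pytest.approx(expected_sd, rel=0.02)
        assert expected_sd == pytest.approx(2.648, rel=1e-3)

    def test_additive_floor_at_zero_prediction(self, pm):
        y = cov.apply_residual_error(np.zeros(100_000), pm, 12)
        assert np.std(y) == pytest.approx(0.0125, rel=0.02)


class TestCVPercent:
    @pytest.mark.parametrize("var,expected", [(0.0547, 23.4), (0.0711, 26.7), (0.0701, 26.5)])
    def test_printed_conversions(self, var, expected):
        assert round(cov.cv_percent(var), 1) == expected

    def test_zero_and_round_trip(self):
        assert cov.cv_percent(0.0) == 0.0
        assert cov.cv_percent(0.123) ** 2 / 1e4 == pytest.approx(0.123, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cov.cv_percent(-0.1)


class TestModelIO:
    def test_default_yaml_reproduces_final_estimates(self, pm):
        assert pm == cov.PopulationModel()

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "m.yaml"
        path.write_text(
            yaml.safe_dump(
                {"cl_gfr_slope": 0.06, "omega2_cl": 0.04, "rhodin": {"tm50": 50.0}}
            )
        )
        m = cov.load_model(path)
        assert m.cl_gfr_slope == 0.06
        assert m.rhodin.tm50 == 50.0
        assert m.v1_ref == 16.1  # unlisted keys keep final-model defaults
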