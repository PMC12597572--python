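"""Covariate engine: individualised parameters, covariate factors and the
log-normal variability bookkeeping."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remipkpd import (
    SubjectCovariates,
    ThetaTable,
    apply_ecmo_icu,
    bis_params,
    cv_from_omega2,
    derive_opioid_cutpoints,
    individual_parameters,
    metab_pk_params,
    moaas_params,
    omega2_from_cv,
    remi_pk_params,
    simplified_remi_params,
)

REF = SubjectCovariates(age=35, weight=70, sex="male")


class TestRemiParams:
    def test_reference_subject_returns_table_values(self, theta):
        p = remi_pk_params(REF, theta)
        # table values are printed to 3 s.f.; compare at that precision
        assert p.V1 == pytest.approx(4.31, rel=3e-3)
        assert p.V2 == pytest.approx(12.3, rel=3e-3)
        assert p.V3 == pytest.approx(18.6, rel=3e-3)
        assert p.CL == pytest.approx(1.12, rel=3e-3)
        assert p.Q2 == pytest.approx(1.45, rel=3e-3)
        assert p.Q3 == pytest.approx(0.298, rel=3e-3)
        assert p.fven == pytest.approx(0.132)
        assert p.kdelay == pytest.approx(0.0144)

    def test_female_with_opioids_matches_printed_code_for_cl(self, theta):
        cov = SubjectCovariates(age=35, weight=70, sex="female",
                                opioids_present=True)
        p = remi_pk_params(cov, theta)
        # oracle: the published simplified code CL=CSIZ*1.11977*exp(KSCL+KOCL)
        expected = 1.11977 * math.exp(0.162802 - 0.139340)
        assert p.CL == pytest.approx(expected, rel=1e-3)

    def test_linear_volume_allometry(self, theta):
        cov = SubjectCovariates(age=35, weight=35, sex="male")
        assert remi_pk_params(cov, theta).V1 == pytest.approx(4.31 * 0.5, rel=1e-3)

    def test_cl_allometric_exponent_0p75(self, theta):
        heavy = SubjectCovariates(age=35, weight=140, sex="male")
        ratio = remi_pk_params(heavy, theta).CL / remi_pk_params(REF, theta).CL
        assert ratio == pytest.approx(2.0 ** 0.75)

    def test_sex_effect_on_cl(self, theta):
        f = SubjectCovariates(age=35, weight=70, sex="female")
        ratio = remi_pk_params(f, theta).CL / remi_pk_params(REF, theta).CL
        assert ratio == pytest.approx(math.exp(0.163), rel=1e-3)

    def test_v3_age_and_q3_compartmental_allometry(self, theta):
        old = SubjectCovariates(age=80, weight=70, sex="male")
        p_old, p_ref = remi_pk_params(old, theta), remi_pk_params(REF, theta)
        assert p_old.V3 > p_ref.V3
        assert p_old.Q3 / p_ref.Q3 == pytest.approx((p_old.V3 / p_ref.V3) ** 0.75)

    def test_eta_applied_lognormally(self, theta):
        eta = np.array([0.1, 0.0, 0.0, -0.2, 0.0, 0.0])
        p = remi_pk_params(REF, theta, eta)
        assert p.V1 == pytest.approx(4.31 * math.exp(0.1), rel=1e-3)
        assert p.CL == pytest.approx(1.12 * math.exp(-0.2), rel=1e-3)

    @pytest.mark.parametrize("age,weight", [(-1, 70), (0, 70), (35, -5), (35, 0)])
    def test_nonpositive_age_or_weight_rejected(self, age, weight):
        with pytest.raises(ValueError):
            SubjectCovariates(age=age, weight=weight)


class TestMetabParams:
    def test_reference_subject(self, theta):
        p = metab_pk_params(REF, theta)
        assert p.CLm == pytest.approx(0.0665)
        assert p.V1m == pytest.approx(6.85)
        assert p.kdepot == pytest.approx(0.215)

    def test_esrd_clearance_factor(self, theta):
        cov = SubjectCovariates(age=35, weight=70, esrd=True)
        assert metab_pk_params(cov, theta).CLm == pytest.approx(
            0.0665 * math.exp(-2.18))

    def test_estimated_volume_scaling_exponent(self, theta):
        cov = SubjectCovariates(age=35, weight=140, sex="male")
        assert metab_pk_params(cov, theta).V1m == pytest.approx(
            6.85 * 2.0 ** 0.518)
        # at reference weight the exponent is irrelevant
        assert metab_pk_params(REF, theta).V1m == pytest.approx(6.85)

    def test_q2_age_and_hepatic_factors(self, theta):
        old_pugh = SubjectCovariates(age=60, weight=70, pugh_gt8=True)
        p = metab_pk_params(old_pugh, theta)
        assert p.Q2m == pytest.approx(
            0.141 * math.exp(15.7 / 1000 * 25) * math.exp(1.88))


class TestPDParams:
    def test_reference_ce50_and_ke0(self, theta):
        m = moaas_params(REF, theta)
        b = bis_params(REF, theta)
        assert m.ce50 == pytest.approx(0.182)
        assert m.ke0 == pytest.approx(0.298, rel=1e-3)
        assert b.ce50 == pytest.approx(0.982)
        assert b.ke0 == pytest.approx(0.145)

    def test_ce50_strictly_decreasing_in_age(self, theta):
        ages = [20, 35, 50, 65, 80]
        m50 = [moaas_params(SubjectCovariates(age=a, weight=70), theta).ce50
               for a in ages]
        b50 = [bis_params(SubjectCovariates(age=a, weight=70), theta).ce50
               for a in ages]
        assert all(np.diff(m50) < 0) and all(np.diff(b50) < 0)

    def test_bis_ke0_decreases_with_age(self, theta):
        young = bis_params(SubjectCovariates(age=20, weight=70), theta)
        old = bis_params(SubjectCovariates(age=80, weight=70), theta)
        assert old.ke0 < young.ke0
        # MOAA/S ke0 carries no covariates
        assert (moaas_params(SubjectCovariates(age=20, weight=70), theta).ke0
                == moaas_params(SubjectCovariates(age=80, weight=70), theta).ke0)


class TestOpioidCutpoints:
    def test_reproduces_footnoted_values(self):
        b0_op, d01_op = derive_opioid_cutpoints(-16.6, 2.65, 1.67)
        assert d01_op == pytest.approx(0.500, abs=2e-3)
        assert float(f"{b0_op:.3g}") == pytest.approx(-14.4)

    def test_identity_at_zero_coefficient(self):
        assert derive_opioid_cutpoints(-16.6, 2.65, 0.0) == (-16.6, 2.65)

    @given(st.floats(-20, 0), st.floats(0, 5), st.floats(-3, 3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cumulative_logit_for_s_leq_1_is_invariant(self, b0, d01, k):
        b0_op, d01_op = derive_opioid_cutpoints(b0, d01, k)
        assert b0_op + d01_op == pytest.approx(b0 + d01, abs=1e-12)
        if k > 0:
            # probability shifts from score 1 toward 0
            assert b0_op >= b0 - 1e-12


class TestEcmoIcu:
    def test_all_flags_false_is_identity(self, theta):
        remi = remi_pk_params(REF, theta)
        metab = metab_pk_params(REF, theta)
        assert apply_ecmo_icu(remi, metab, REF, theta) == (remi, metab)

    def test_active_ecmo_v1_factor(self, theta):
        cov = SubjectCovariates(age=35, weight=70, ecmo_subject=True,
                                ecmo_active=True)
        remi = remi_pk_params(cov, theta)
        adj, _ = apply_ecmo_icu(remi, metab_pk_params(cov, theta), cov, theta)
        assert adj.V1 == pytest.approx(remi.V1 * 46.1 * 0.189)
        assert adj.V2 == pytest.approx(remi.V2 * 0.189)
        assert adj.CL == pytest.approx(remi.CL * 0.815)

    def test_icu_adjustments(self, theta):
        cov = SubjectCovariates(age=35, weight=70, icu_subject=True,
                                icu_gt24h=True)
        remi = remi_pk_params(cov, theta)
        metab = metab_pk_params(cov, theta)
        adj_r, adj_m = apply_ecmo_icu(remi, metab, cov, theta)
        assert adj_r.V3 == pytest.approx(remi.V3 * 1.59)
        assert adj_r.CL == pytest.approx(remi.CL * 0.264)
        assert adj_m.CLm == pytest.approx(metab.CLm * 0.426)


class TestCVConversion:
    @pytest.mark.parametrize("omega2,cv", [
        (0.0631, 25.5), (0.0297, 17.4), (0.443, 74.7),
        (0.145, 39.5), (0.549, 85.5), (0.228, 50.6),
    ])
    def test_published_cv_cells(self, omega2, cv):
        assert round(cv_from_omega2(omega2), 1) == cv

    def test_zero_maps_to_zero(self):
        assert cv_from_omega2(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_from_omega2(-0.1)

    @given(st.floats(0, 3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_roundtrip_and_monotonicity(self, w2):
        assert omega2_from_cv(cv_from_omega2(w2)) == pytest.approx(w2, abs=1e-12)
        assert cv_from_omega2(w2 + 0.01) > cv_from_omega2(w2)


class TestSimplifiedCode:
    def test_printed_reference_values(self):
        p = simplified_remi_params(35, 70, "male", False)
        assert p.V3 == pytest.approx(18.6411)
        assert p.CL == pytest.approx(1.11977)
        assert p.V1 == pytest.approx(4.30730)

    def test_cross_oracle_equivalence(self, theta):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(300):
            cov = SubjectCovariates(
                age=float(rng.uniform(6, 93)), weight=float(rng.uniform(21, 171)),
                sex="female" if rng.random() < 0.5 else "male",
                opioids_present=bool(rng.random() < 0.5),
            )
            full = remi_pk_params(cov, theta)
            simp = simplified_remi_params(cov.age, cov.weight, cov.sex,
                                          cov.opioids_present)
            for name in ("V1", "V2", "V3", "CL", "Q2", "Q3"):
                rel = abs(getattr(full, name) / getattr(simp, name) - 1)
                worst = max(worst, rel)
        assert worst < 2e-3

    def test_size_scalars_unity_at_reference(self):
        p = simplified_remi_params(35, 70, "male", False)
        assert p.V1 / 4.30730 == pytest.approx(1.0)
        assert p.CL / 1.11977 == pytest.approx(1.0)


class TestPositivityAndStructure:
    @given(st.floats(6, 93), st.floats(21, 171), st.booleans(), st.booleans(),
           st.booleans(), st.booleans())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_all_parameters_strictly_positive(self, age, weight, female,
                                              opioids, pugh, esrd):
        cov = SubjectCovariates(age=age, weight=weight,
                                sex="female" if female else "male",
                                opioids_present=opioids, pugh_gt8=pugh,
                                esrd=esrd)
        m = individual_parameters(cov)
        assert min(m.remi.V1, m.remi.V2, m.remi.V3, m.remi.CL, m.remi.Q2,
                   m.remi.Q3) > 0
        assert min(m.metab.kdepot, m.metab.V1m, m.metab.V2m, m.metab.CLm,
                   m.metab.Q2m) > 0
        assert m.moaas.ce50 > 0 and m.bis.ce50 > 0 and m.bis.ke0 > 0

    def test_invalid_flag_combinations_rejected(self):
        with pytest.raises(ValueError):
            SubjectCovariates(age=35, weight=70, ecmo_active=True)
        with pytest.raises(ValueError):
            SubjectCovariates(age=35, weight=70, icu_gt24h=True)

    def test_wrong_eta_length_rejected(self, theta):
        with pytest.raises(ValueError):
            remi_pk_params(REF, theta, np.zeros(5))
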