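"""Structural and covariate model: FFM, maturation, concentrations, AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from busulfan_mipd import (
    ConfigurationError,
    InvalidCovariateError,
    InvalidInputError,
    PatientCovariates,
    PopulationModel,
    Regimen,
    analytic_course_auc,
    build_regimen,
    compute_ffm,
    default_model,
    maturation_factor,
    predict_concentration,
    simulate_observations,
    typical_parameters,
)
from busulfan_mipd.model import DoseEvent, IndividualParameters


def ode_concentration(ip, reg, t_eval):
    """Independent oracle: numerically integrate dC/dt = rate/V - ke*C."""
    def rhs(t, y):
        rate = sum(
            d.amount / d.duration
            for d in reg.doses
            if d.start_time < t <= d.start_time + d.duration
        )
        return [rate / ip.v - (ip.cl / ip.v) * y[0]]

    breaks = sorted(
        {0.0, *[d.start_time for d in reg.doses],
         *[d.start_time + d.duration for d in reg.doses], *t_eval}
    )
    sol = solve_ivp(rhs, (0.0, max(t_eval)), [0.0], t_eval=sorted(t_eval),
                    rtol=1e-11, atol=1e-13, max_step=0.25)
    return sol.y[0]


class TestFfm:
    def test_janmahasatian_male_hand_calculation(self):
        cov = PatientCovariates("m", age=30, weight=70, height=176, sex="male")
        bmi = 70 / 1.76**2
        expected = 9270 * 70 / (6680 + 216 * bmi)
        assert compute_ffm(cov) == pytest.approx(expected, rel=1e-12)

    def test_janmahasatian_female_hand_calculation(self):
        cov = PatientCovariates("f", age=30, weight=60, height=165, sex="female")
        bmi = 60 / 1.65**2
        expected = 9270 * 60 / (8780 + 244 * bmi)
        assert compute_ffm(cov) == pytest.approx(expected, rel=1e-12)

    def test_fallback_is_weight_fraction(self):
        cov = PatientCovariates("nb", age=1.0, weight=10.0, sex="male")
        assert compute_ffm(cov, fallback_fraction=0.85) == pytest.approx(8.5)

    @given(
        weight=st.floats(2.0, 150.0),
        height=st.floats(45.0, 200.0),
        age=st.floats(0.0, 40.0),
        sex=st.sampled_from(["male", "female"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_body_weight(self, weight, height, age, sex):
        cov = PatientCovariates("h", age=age, weight=weight, height=height, sex=sex)
        ffm = compute_ffm(cov)
        assert 0 < ffm <= weight

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(InvalidCovariateError):
            PatientCovariates("bad", age=1.0, weight=0.0, sex="male")


class TestMaturation:
    def test_half_maximal_at_tm50(self, model):
        assert maturation_factor(model.tm50, model) == pytest.approx(0.5)

    def test_zero_at_birth(self, model):
        assert maturation_factor(0.0, model) == 0.0

    def test_asymptote(self):
        m = default_model(tm50=0.5, hill=2.0)
        assert maturation_factor(50.0, m) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_and_bounded(self, model):
        ages = np.linspace(0, 30, 200)
        vals = [maturation_factor(a, model) for a in ages]
        assert all(0 <= v < 1 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_age_rejected(self, model):
        with pytest.raises(InvalidCovariateError):
            maturation_factor(-0.1, model)


class TestTypicalParameters:
    def test_identity_at_reference(self):
        m = default_model()
        # weight chosen so the fallback FFM equals the reference FFM exactly
        cov = PatientCovariates("ref", age=1e6, weight=m.ffm_ref / 0.85,
                                sex="male", regimen_label=m.reference_regimen)
        ip = typical_parameters(m, cov)
        assert ip.cl == pytest.approx(m.theta_cl, rel=1e-9)
        assert ip.v == pytest.approx(m.theta_v, rel=1e-9)

    def test_allometric_power_law(self):
        m = default_model()
        cov = PatientCovariates("half", age=1e6, weight=m.ffm_ref / 2 / 0.85,
                                sex="male")
        ip = typical_parameters(m, cov)
        assert ip.cl == pytest.approx(m.theta_cl * 0.5**0.75, rel=1e-9)

    def test_regimen_factor_multiplies_cl(self):
        m = default_model(regimen_factors={"bu_flu": 1.0, "other": 0.8})
        ref = PatientCovariates("a", age=1000.0, weight=20, sex="male",
                                regimen_label="bu_flu")
        alt = PatientCovariates("b", age=1000.0, weight=20, sex="male",
                                regimen_label="other")
        assert typical_parameters(m, alt).cl == pytest.approx(
            0.8 * typical_parameters(m, ref).cl, rel=1e-12
        )

    def test_unknown_regimen_label_rejected(self, model):
        cov = PatientCovariates("x", age=3.0, weight=15.0, sex="male",
                                regimen_label="unheard-of")
        with pytest.raises(ConfigurationError):
            typical_parameters(model, cov)


class TestPredictConcentration:
    def test_end_of_infusion_closed_form(self):
        ip = IndividualParameters(cl=2.5, v=15.0)
        reg = Regimen(doses=(DoseEvent(0.0, 20.0, 2.0),), interval=24, n_days=2)
        ke = 2.5 / 15.0
        expected = (10.0 / 2.5) * (1 - math.exp(-ke * 2.0))
        assert predict_concentration(ip, reg, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_matches_ode_oracle_single_dose(self):
        ip = IndividualParameters(cl=2.5, v=15.0)
        reg = Regimen(doses=(DoseEvent(0.0, 20.0, 2.0),), interval=24, n_days=2)
        times = [0.5, 1.0, 2.0, 3.0, 6.0, 12.0]
        closed = np.array([predict_concentration(ip, reg, t) for t in times])
        numeric = ode_concentration(ip, reg, times)
        assert np.max(np.abs(closed - numeric) / numeric) < 1e-6

    def test_zero_before_first_dose(self, q6_regimen):
        ip = IndividualParameters(cl=3.0, v=12.0)
        assert predict_concentration(ip, q6_regimen, 0.0) == 0.0

    def test_linearity_in_dose(self, q6_regimen):
        ip = IndividualParameters(cl=3.0, v=12.0)
        doubled = Regimen(
            doses=tuple(DoseEvent(d.start_time, 2 * d.amount, d.duration)
                        for d in q6_regimen.doses),
            interval=q6_regimen.interval, n_days=q6_regimen.n_days,
        )
        for t in (1.0, 5.5, 26.0, 80.0):
            assert predict_concentration(ip, doubled, t) == pytest.approx(
                2 * predict_concentration(ip, q6_regimen, t), rel=1e-12
            )


class TestCourseAuc:
    def test_total_auc_is_dose_over_cl(self, q6_regimen):
        ip = IndividualParameters(cl=2.5, v=15.0)
        assert analytic_course_auc(ip, q6_regimen) == pytest.approx(160.0 / 2.5, rel=1e-14)

    def test_window_converges_to_total(self, q6_regimen):
        ip = IndividualParameters(cl=2.5, v=15.0)
        total = analytic_course_auc(ip, q6_regimen)
        windowed = analytic_course_auc(ip, q6_regimen, window=(0.0, 2000.0))
        assert windowed == pytest.approx(total, rel=1e-10)

    def test_window_matches_quadrature(self, rng):
        from scipy.integrate import quad

        ip = IndividualParameters(cl=3.1, v=11.0)
        amounts = rng.uniform(5, 20, size=16)
        doses = tuple(
            DoseEvent(6.0 * i, float(a), 2.0) for i, a in enumerate(amounts)
        )
        reg = Regimen(doses=doses, interval=6, n_days=4)
        t1, t2 = 3.0, 96.0
        closed = analytic_course_auc(ip, reg, window=(t1, t2))
        pts = sorted({d.start_time for d in doses} | {d.start_time + 2.0 for d in doses})
        numeric = 0.0
        edges = [t1] + [p for p in pts if t1 < p < t2] + [t2]
        for a, b in zip(edges, edges[1:]):
            val, _ = quad(lambda t: predict_concentration(ip, reg, t), a, b,
                          limit=200, epsabs=1e-12, epsrel=1e-10)
            numeric += val
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_iov_splits_auc_by_day(self):
        occ = (0.2, -0.1, 0.0, 0.3)
        ip = IndividualParameters(cl=3.0, v=12.0, occasion_etas=occ)
        reg = build_regimen(10.0, 6, 4)
        expected = sum(40.0 / (3.0 * math.exp(occ[d])) for d in range(4))
        assert analytic_course_auc(ip, reg) == pytest.approx(expected, rel=1e-12)


class TestSimulateObservations:
    def test_noiseless_limit_equals_prediction(self, q6_regimen):
        m = default_model(sigma_prop=0.0, sigma_add=0.0)
        ip = IndividualParameters(cl=3.0, v=12.0)
        obs = simulate_observations(ip, q6_regimen, [3.0, 5.0, 22.0], m, seed=1)
        for o in obs:
            assert o.concentration == pytest.approx(
                predict_concentration(ip, q6_regimen, o.time), rel=1e-12
            )
            assert not o.below_lloq

    def test_seed_determinism(self, model, q6_regimen):
        ip = IndividualParameters(cl=3.0, v=12.0)
        a = simulate_observations(ip, q6_regimen, [3.0, 5.0], model, seed=7)
        b = simulate_observations(ip, q6_regimen, [3.0, 5.0], model, seed=7)
        assert a == b

    def test_proportional_error_cv_monte_carlo(self, q6_regimen):
        m = default_model(sigma_prop=0.1, sigma_add=0.0)
        ip = IndividualParameters(cl=3.0, v=12.0)
        f = predict_concentration(ip, q6_regimen, 5.0)
        rng = np.random.default_rng(123)
        ys = [
            simulate_observations(ip, q6_regimen, [5.0], m, rng)[0].concentration
            for _ in range(10_000)
        ]
        cv = np.std(np.array(ys) / f, ddof=1)
        assert abs(cv - 0.1) < 0.005

    def test_empty_times_rejected(self, model, q6_regimen):
        ip = IndividualParameters(cl=3.0, v=12.0)
        with pytest.raises(InvalidInputError):
            simulate_observations(ip, q6_regimen, [], model, seed=1)


class TestPopulationModelValidation:
    def test_asymmetric_omega_rejected(self):
        with pytest.raises(ConfigurationError):
            default_model(omega=np.array([[0.04, 0.1], [0.0, 0.04]]))

    def test_indefinite_omega_rejected(self):
        with pytest.raises(ConfigurationError):
            default_model(omega=np.array([[0.01, 0.05], [0.05, 0.01]]))

    def test_reference_regimen_must_be_unity(self):
        with pytest.raises(ConfigurationError):
            default_model(regimen_factors={"bu_flu": 0.9})
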