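"""MAP estimation, EBE cumulative AUC, and remaining-dose optimization."""

import numpy as np
import pytest

from busulfan_mipd import (
    DoseGrid,
    ExposureTarget,
    InvalidInputError,
    Regimen,
    build_regimen,
    default_model,
    estimate_course_cauc,
    map_estimate,
    recommend_remaining_doses,
    simulate_observations,
    typical_parameters,
)
from busulfan_mipd.bayes import map_objective
from busulfan_mipd.model import individual_from_eta


@pytest.fixture
def rich_times():
    """Three samples per day over days 1-3 of a q6 course."""
    return [d * 24.0 + t for d in range(3) for t in (2.25, 3.0, 5.5)]


class TestMapEstimate:
    def test_no_observations_returns_prior_mode(self, model, child_cov, q6_regimen):
        est = map_estimate(model, child_cov, q6_regimen, [])
        typ = typical_parameters(model, child_cov)
        assert np.allclose(est.eta_hat, 0.0)
        assert est.ip.cl == pytest.approx(typ.cl)
        assert est.ip.v == pytest.approx(typ.v)

    def test_recovers_known_eta_from_dense_noiseless_data(self, child_cov, q6_regimen):
        m = default_model(omega=np.array([[1.0, 0.0], [0.0, 1.0]]), sigma_prop=0.05)
        truth = individual_from_eta(m, child_cov, [0.3, -0.1])
        times = np.arange(1.0, 96.0, 1.5)
        noiseless = default_model(sigma_prop=0.0, sigma_add=0.0,
                                  omega=np.array([[1.0, 0.0], [0.0, 1.0]]))
        obs = simulate_observations(truth, q6_regimen, times, noiseless, seed=0)
        est = map_estimate(m, child_cov, q6_regimen, obs)
        assert est.ip.cl == pytest.approx(truth.cl, rel=0.01)

    def test_degenerate_prior_pins_eta_at_zero(self, child_cov, q6_regimen):
        m = default_model(omega=np.zeros((2, 2)))
        obs = [type(o)(o.time, o.concentration * 3.0) for o in simulate_observations(
            typical_parameters(default_model(), child_cov), q6_regimen, [3.0],
            default_model(sigma_prop=0.0, sigma_add=0.0), seed=0)]
        est = map_estimate(m, child_cov, q6_regimen, obs)
        assert np.allclose(est.eta_hat, 0.0)

    def test_local_optimality_probe(self, model, child_cov, q6_regimen, rich_times):
        truth = individual_from_eta(model, child_cov, [0.25, 0.1])
        obs = simulate_observations(truth, q6_regimen, rich_times, model, seed=11)
        est = map_estimate(model, child_cov, q6_regimen, obs)
        om_inv = np.linalg.inv(model.omega)
        f_hat = map_objective(est.eta_hat, model, child_cov, q6_regimen, obs, om_inv)
        assert f_hat <= map_objective(np.zeros(2), model, child_cov, q6_regimen, obs,
                                      om_inv) + 1e-9
        rng = np.random.default_rng(5)
        for _ in range(32):
            probe = est.eta_hat + rng.normal(0, 0.02, size=2)
            assert f_hat <= map_objective(probe, model, child_cov, q6_regimen, obs,
                                          om_inv) + 1e-9

    def test_wider_prior_never_shrinks_more(self, model, child_cov, q6_regimen):
        truth = individual_from_eta(model, child_cov, [0.4, 0.0])
        obs = simulate_observations(truth, q6_regimen, [3.0], model, seed=3)
        est_tight = map_estimate(model, child_cov, q6_regimen, obs)
        wide = default_model(omega=100.0 * np.asarray(model.omega))
        est_wide = map_estimate(wide, child_cov, q6_regimen, obs)
        assert np.linalg.norm(est_tight.eta_hat) <= np.linalg.norm(est_wide.eta_hat) + 1e-9

    def test_all_zero_concentrations_rejected(self, model, child_cov, q6_regimen):
        from busulfan_mipd import ConcObservation, EstimationError
        obs = [ConcObservation(3.0, 0.0, below_lloq=True)]
        with pytest.raises(EstimationError):
            map_estimate(model, child_cov, q6_regimen, obs)


class TestCourseCauc:
    def test_four_equal_days_scale_day_one(self, model, child_cov, q6_regimen):
        est = map_estimate(model, child_cov, q6_regimen, [])
        cauc = estimate_course_cauc(est, q6_regimen)
        assert cauc == pytest.approx(4 * est.per_day_auc[0], rel=1e-12)

    def test_equals_total_dose_over_cl(self, model, child_cov, q6_regimen):
        est = map_estimate(model, child_cov, q6_regimen, [])
        cauc = estimate_course_cauc(est, q6_regimen)
        assert cauc == pytest.approx(160.0 / est.ip.cl, rel=1e-12)

    def test_matches_long_horizon_quadrature(self, model, child_cov, q6_regimen):
        from busulfan_mipd import analytic_course_auc

        est = map_estimate(model, child_cov, q6_regimen, [])
        cauc = estimate_course_cauc(est, q6_regimen)
        windowed = analytic_course_auc(est.ip, q6_regimen, window=(0.0, 3000.0))
        assert cauc == pytest.approx(windowed, rel=1e-4)

    def test_marks_unobserved_days_as_extrapolated(self, model, child_cov, q6_regimen):
        est = map_estimate(model, child_cov, q6_regimen, [])
        estimate_course_cauc(est, q6_regimen, observed_days={1, 2, 3})
        assert est.extrapolated_days == [4]


def _estimate_with_cl(cl):
    from busulfan_mipd import IndividualEstimate
    from busulfan_mipd.model import IndividualParameters
    return IndividualEstimate(eta_hat=np.zeros(2),
                              ip=IndividualParameters(cl=cl, v=12.0),
                              objective_value=0.0)


class TestRecommendation:
    def test_worked_example(self, model, child_cov):
        reg_so_far = build_regimen(7.5, 6, 4)
        est = _estimate_with_cl(2.0)
        given = Regimen(doses=reg_so_far.doses[:8], interval=6, n_days=4)
        # accrued = 8 * 7.5 / 2 = 30; target 70 -> remaining 40 over 8 doses
        slots = [(d.start_time, d.duration) for d in reg_so_far.doses[8:]]
        rec = recommend_remaining_doses(model, est, ExposureTarget(70.0), given,
                                        slots, DoseGrid(5.0, 20.0, 0.1))
        assert rec.per_dose_amount == pytest.approx(10.0)
        assert rec.predicted_cauc == pytest.approx(70.0)
        assert not rec.saturated

    def test_matches_exhaustive_search(self, model, child_cov):
        rng = np.random.default_rng(77)
        for _ in range(100):
            cl = rng.uniform(1.0, 8.0)
            est0 = _estimate_with_cl(cl)
            base = build_regimen(rng.uniform(2, 20), 6, 4)
            n_given = rng.integers(4, 13)
            given = Regimen(doses=base.doses[:n_given], interval=6, n_days=4)
            slots = [(d.start_time, d.duration) for d in base.doses[n_given:]]
            target = ExposureTarget(rng.uniform(30, 110))
            grid = DoseGrid(rng.uniform(0.5, 3), rng.uniform(10, 25), 0.1)
            rec = recommend_remaining_doses(model, est0, target, given, slots, grid)
            # independent brute force over the same candidates
            accrued = sum(d.amount for d in given.doses) / cl
            best_amt, best_err = None, np.inf
            for amt in grid.amounts():
                pred = accrued + len(slots) * amt / cl
                err = abs(pred - target.cauc_target)
                if err < best_err - 1e-15:
                    best_amt, best_err = amt, err
            assert rec.per_dose_amount == pytest.approx(best_amt)

    def test_target_already_met_saturates_low(self, model, child_cov):
        est = _estimate_with_cl(2.0)
        given = build_regimen(10, 6, 4)
        given = Regimen(doses=given.doses[:8], interval=6, n_days=4)
        slots = [(48.0 + 6 * k, 2.0) for k in range(8)]
        # accrued = 80/2 = 40 == target
        rec = recommend_remaining_doses(model, est, ExposureTarget(40.0), given,
                                        slots, DoseGrid(1.0, 20.0, 0.1))
        assert rec.per_dose_amount == pytest.approx(1.0)
        assert rec.saturated

    def test_no_remaining_slots_rejected(self, model, child_cov):
        est = map_estimate(model, child_cov, build_regimen(10, 6, 4), [])
        with pytest.raises(InvalidInputError):
            recommend_remaining_doses(model, est, ExposureTarget(80.0),
                                      build_regimen(10, 6, 4), [],
                                      DoseGrid(1.0, 20.0, 0.1))
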