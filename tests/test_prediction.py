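"""Dynamic event-free prediction: invariants and estimator oracles."""

from dataclasses import replace

import numpy as np
import pytest

from bnpjm import (
    JointConfig,
    JointModelFit,
    JointParameters,
    SubjectHistory,
    WeibullBaseline,
    predict_event_free,
    update_prediction,
)
from bnpjm.errors import ChronologyError, DomainError
from bnpjm.joint import subject_design
from bnpjm.simulate import TRUTH_SCALING

JONES = dict(ava=0.96, age=72.0, symptoms=0, male=1, lvef=61.0,
             creatinine=92.0)
JONES_MEAS = ((0.5, 64.0), (0.9, 70.0), (1.5, 72.0), (1.5, 78.0))


@pytest.fixture()
def jones_history():
    return SubjectHistory(covariates=JONES, measurements=JONES_MEAS, t=1.5)


class TestSubjectHistory:
    def test_out_of_order_measurements_rejected(self):
        with pytest.raises(ChronologyError):
            SubjectHistory(JONES, ((1.0, 70.0), (0.5, 64.0)), t=1.5)

    def test_measurement_after_t_rejected(self):
        with pytest.raises(DomainError):
            SubjectHistory(JONES, ((2.0, 70.0),), t=1.5)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(DomainError):
            SubjectHistory(JONES, ((0.5, 0.0),), t=1.5)


class TestPredictEventFree:
    def test_probability_one_at_conditioning_time(self, fit_death150,
                                                  jones_history):
        u = np.array([1.5, 2.0, 3.0])
        for method in ("first-order", "mc"):
            curve = predict_event_free(fit_death150, jones_history, u_grid=u,
                                       n_mc=200, seed=1, method=method)
            assert curve.pi[0] == 1.0
            assert curve.lower[0] == 1.0 and curve.upper[0] == 1.0

    def test_curve_invariants(self, fit_death150, jones_history):
        curve = predict_event_free(fit_death150, jones_history, n_mc=300,
                                   seed=2)
        assert np.all(np.diff(curve.pi) <= 1e-12)      # non-increasing
        assert np.all((curve.pi >= 0) & (curve.pi <= 1))
        assert np.all(curve.lower <= curve.pi + 1e-12)
        assert np.all(curve.pi <= curve.upper + 1e-12)

    def test_seed_reproducibility_bitwise(self, fit_death150, jones_history):
        a = predict_event_free(fit_death150, jones_history, n_mc=150, seed=9)
        b = predict_event_free(fit_death150, jones_history, n_mc=150, seed=9)
        np.testing.assert_array_equal(a.pi, b.pi)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_horizon_before_t_rejected(self, fit_death150, jones_history):
        with pytest.raises(DomainError):
            predict_event_free(fit_death150, jones_history,
                               u_grid=np.array([1.0]))

    def test_severed_link_matches_weibull_ratio(self, fit_death150,
                                                jones_history):
        """alpha = 0: pi(u|t) is the closed-form Weibull-PH ratio, exactly
        for every Monte-Carlo draw (so also for the mean)."""
        params = replace(fit_death150.params, alpha=0.0)
        fit0 = replace(fit_death150, params=params,
                       theta=np.array(fit_death150.theta, copy=True),
                       vcov=np.zeros_like(fit_death150.vcov))
        fit0.theta[18] = 0.0  # alpha entry of the packed vector
        u = np.array([2.0, 2.5, 3.5])
        curve = predict_event_free(fit0, jones_history, u_grid=u, n_mc=100,
                                   seed=3)
        w, _ = subject_design(JONES, fit_death150.scaling_constants)
        bl = params.baseline
        t = jones_history.t
        closed = np.exp(-(((u / bl.scale) ** bl.shape
                           - (t / bl.scale) ** bl.shape))
                        * np.exp(w @ params.gamma))
        np.testing.assert_allclose(curve.pi, closed, atol=1e-10)

    def test_mc_agrees_with_quadrature_oracle(self, fit_death150,
                                              jones_history):
        """theta fixed (vcov = 0): MC estimator vs deterministic 2-D
        quadrature over the random-effect posterior."""
        fit_fixed = replace(fit_death150,
                            vcov=np.zeros_like(fit_death150.vcov))
        u = np.array([2.0, 3.0, 4.0])
        mc = predict_event_free(fit_fixed, jones_history, u_grid=u,
                                n_mc=4000, seed=5)
        quad = predict_event_free(fit_death150, jones_history, u_grid=u,
                                  method="first-order", nodes=21)
        assert np.all(np.abs(mc.pi - quad.pi) < 3 * mc.mc_se + 1e-12)

    def test_mc_convergence_with_more_draws(self, fit_death150,
                                            jones_history):
        u = np.array([2.0, 3.0])
        a = predict_event_free(fit_death150, jones_history, u_grid=u,
                               n_mc=2000, seed=6)
        b = predict_event_free(fit_death150, jones_history, u_grid=u,
                               n_mc=4000, seed=7)
        combined = np.sqrt(a.mc_se ** 2 + b.mc_se ** 2)
        assert np.all(np.abs(a.pi - b.pi) < 3 * combined)

    def test_empty_history_gives_population_prediction(self, fit_death150):
        hist = SubjectHistory(covariates=JONES, measurements=(), t=0.0)
        curve = predict_event_free(fit_death150, hist, method="first-order")
        assert curve.pi[0] == 1.0
        assert np.all(np.diff(curve.pi) <= 1e-12)

    def test_surviving_longer_without_news_is_good_news(self, fit_death150):
        """pi(u | t2) >= pi(u | t1) for t2 > t1, same measurements."""
        meas = ((0.0, 80.0), (0.5, 90.0))
        h1 = SubjectHistory(JONES, meas, t=0.5)
        h2 = SubjectHistory(JONES, meas, t=1.5)
        u = np.linspace(2.0, 4.0, 9)
        pi1 = predict_event_free(fit_death150, h1, u_grid=u,
                                 method="first-order").pi
        pi2 = predict_event_free(fit_death150, h2, u_grid=u,
                                 method="first-order").pi
        assert np.all(pi2 >= pi1 - 1e-9)


class TestUpdatePrediction:
    def test_chronology_enforced(self, fit_death150, jones_history):
        with pytest.raises(ChronologyError):
            update_prediction(fit_death150, jones_history, (1.0, 75.0))

    def test_on_trajectory_update_moves_curve_less_than_outlier(
            self, fit_death150):
        """Appending the model-expected value shifts the curve less than
        appending a value 3 residual SDs higher."""
        from bnpjm.prediction import _eb_mode, _neg_log_posterior

        params = fit_death150.params
        hist = SubjectHistory(JONES, ((0.0, 70.0), (0.5, 75.0)), t=0.5)
        w, base_row = subject_design(JONES, fit_death150.scaling_constants)
        mode, _, _ = _eb_mode(params, w, base_row, hist.times,
                              hist.values_log, hist.t)
        t_new = 1.0
        mu = (params.beta[0] + base_row @ params.beta[2:]
              + params.beta[1] * t_new + mode[0] + mode[1] * t_new)
        expected = float(np.exp(mu))
        outlier = float(np.exp(mu + 3 * np.sqrt(params.sigma2)))
        u = np.linspace(1.0, 3.0, 21)
        base = predict_event_free(fit_death150, hist.with_measurement(
            t_new, expected), u_grid=u, method="first-order").pi
        shifted = predict_event_free(fit_death150, hist.with_measurement(
            t_new, outlier), u_grid=u, method="first-order").pi
        ref = predict_event_free(
            fit_death150,
            SubjectHistory(JONES, hist.measurements, t=t_new),
            u_grid=u, method="first-order").pi
        assert np.linalg.norm(base - ref) < np.linalg.norm(shifted - ref)

    def test_stable_low_history_changes_little(self, fit_death150):
        """A flat low-BNP history: successive curves nearly coincide."""
        hist = SubjectHistory(JONES, JONES_MEAS[:2], t=0.9)
        u = np.linspace(2.0, 3.5, 16)
        before = predict_event_free(fit_death150, hist, u_grid=u,
                                    method="first-order").pi
        hist2, _ = update_prediction(fit_death150, hist, (1.5, 72.0),
                                     u_grid=u, method="first-order")
        after = predict_event_free(fit_death150, hist2, u_grid=u,
                                   method="first-order").pi
        assert np.max(np.abs(after - before)) < 0.1

    def test_rising_high_history_lowers_event_free_probability(
            self, fit_death150):
        """Under a positive association, a sharply higher BNP measurement
        lowers the predicted event-free probability at a fixed horizon."""
        assert fit_death150.params.alpha > 0  # fixture premise
        smith = dict(ava=0.61, age=79.0, symptoms=1, male=1, lvef=61.0,
                     creatinine=92.0)
        hist = SubjectHistory(smith, ((0.0, 381.0), (0.9, 287.0)), t=0.9)
        u = np.array([3.0])
        before = predict_event_free(fit_death150, hist, u_grid=u,
                                    method="first-order").pi[0]
        hist2, _ = update_prediction(fit_death150, hist, (1.2, 1068.0),
                                     u_grid=u, method="first-order")
        after = predict_event_free(fit_death150, hist2, u_grid=u,
                                   method="first-order").pi[0]
        assert after < before
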