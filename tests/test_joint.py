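"""Joint model: likelihood oracles, estimation, survival machinery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bnpjm import (
    JointConfig,
    JointModelFit,
    JointParameters,
    WeibullBaseline,
    conditional_survival,
    fit_joint,
    fit_lmm,
    joint_loglik,
    preprocess,
)
from bnpjm.errors import DegenerateOutcomeError, DomainError, SchemaError
from bnpjm.simulate import TRUTH_SCALING, default_truth, simulate_cohort

from oracles import lmm_marginal_loglik, mc_joint_loglik, weibull_ph_loglik


def severed(params):
    return replace(params, alpha=0.0)


class TestJointLoglik:
    def test_factorizes_when_link_severed(self, truth, cohort20):
        """alpha = 0: joint loglik = LMM marginal + parametric PH loglik."""
        p0 = severed(truth.params_death)
        oracle = (lmm_marginal_loglik(p0, cohort20)
                  + weibull_ph_loglik(p0, cohort20, "death"))
        value = joint_loglik(p0, cohort20, "death", nodes=9,
                             quadrature="pseudo-adaptive")
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_matches_monte_carlo_integration(self, truth, cohort20):
        """Full-link likelihood vs 20k-draw MC integration over b."""
        p = truth.params_death
        mc, mc_se = mc_joint_loglik(p, cohort20, "death", n_draws=20_000,
                                    seed=4)
        gh = joint_loglik(p, cohort20, "death", nodes=25)
        assert abs(gh - mc) < 3 * mc_se

    def test_subject_without_measurements_contributes_survival_term(
            self, truth, cohort20):
        """An empty longitudinal history reduces to the survival integral."""
        cohort = cohort20.copy()
        sid = cohort.survival["subject_id"].iloc[0]
        cohort.longitudinal = cohort.longitudinal[
            cohort.longitudinal["subject_id"] != sid].reset_index(drop=True)
        p = truth.params_death
        per = joint_loglik(p, cohort, "death", nodes=25, per_subject=True)
        # oracle: MC integral of the survival density alone for that subject
        rng = np.random.default_rng(11)
        L = np.linalg.cholesky(p.D)
        b = rng.standard_normal((200_000, 2)) @ L.T
        row = cohort.survival.iloc[0]
        from bnpjm.joint import subject_design

        covs = {k: row[k] for k in ("ava", "age", "symptoms", "male", "lvef",
                                    "creatinine")}
        w, base_row = subject_design(covs, TRUTH_SCALING)
        m_fix = p.beta[0] + base_row @ p.beta[2:]
        eta = w @ p.gamma + p.alpha * (m_fix + b[:, 0])
        c = p.alpha * (p.beta[1] + b[:, 1])
        H = np.exp(eta) * p.baseline.exp_integral(c, row["obs_time"])
        log_h = p.baseline.log_h0(row["obs_time"]) + eta + c * row["obs_time"]
        lik = np.exp(row["status_death"] * log_h - H)
        mc = np.log(lik.mean())
        mc_se = lik.std(ddof=1) / np.sqrt(lik.size) / lik.mean()
        assert abs(per[0] - mc) < 3 * mc_se

    def test_quadrature_refinement_converged(self, truth, cohort20):
        p = truth.params_death
        ll15 = joint_loglik(p, cohort20, "death", nodes=15,
                            quadrature="pseudo-adaptive")
        ll21 = joint_loglik(p, cohort20, "death", nodes=21,
                            quadrature="pseudo-adaptive")
        assert abs(ll21 - ll15) / abs(ll15) < 1e-5

    def test_rejects_bad_inputs(self, truth, cohort20):
        with pytest.raises(SchemaError):
            joint_loglik(truth.params_death, cohort20, "relapse")
        bad = replace(truth.params_death, sigma2=-1.0)
        with pytest.raises(DomainError):
            joint_loglik(bad, cohort20, "death")


class TestFitJoint:
    def test_recovers_generating_parameters(self, truth):
        """n=300 cohort from the default truth: estimates within 3 SE."""
        cohort = preprocess(simulate_cohort(truth, 300, seed=11),
                            constants=TRUTH_SCALING)
        fit = fit_joint(cohort, "death",
                        JointConfig(nodes=9, quadrature="pseudo-adaptive"))
        p, pt = fit.params, truth.params_death
        assert fit.converged
        assert abs(p.alpha - pt.alpha) < 3 * fit.se("alpha")[0]
        assert np.all(np.abs(p.gamma - pt.gamma) < 3 * fit.se("gamma"))
        assert np.all(np.abs(p.beta - pt.beta) < 3 * fit.se("beta"))
        # optimization improved on the two-stage initializer
        assert fit.loglik >= fit.init_loglik - 1e-6

    def test_null_association_recovered(self, truth):
        """Data simulated with alpha = 0: alpha's Wald z stays small and
        the longitudinal part agrees with the standalone mixed model."""
        null = default_truth()
        null.params_death = replace(
            null.params_death, alpha=0.0,
            baseline=WeibullBaseline(shape=1.2, scale=70.0))
        null.params_intervention = replace(null.params_intervention,
                                           alpha=0.0)
        cohort = preprocess(simulate_cohort(null, 200, seed=13),
                            constants=TRUTH_SCALING)
        fit = fit_joint(cohort, "death",
                        JointConfig(nodes=9, quadrature="pseudo-adaptive"))
        z = fit.params.alpha / fit.se("alpha")[0]
        assert abs(z) < 3
        lmm = fit_lmm(cohort)
        assert np.all(np.abs(fit.params.beta - lmm.beta)
                      < 2 * lmm.se_beta + 1e-6)

    def test_stable_under_quadrature_refinement(self, cohort150):
        fits = [fit_joint(cohort150, "death",
                          JointConfig(nodes=k, quadrature="pseudo-adaptive",
                                      compute_vcov=False))
                for k in (9, 15)]
        a, b = fits
        assert abs(a.params.alpha - b.params.alpha) < 0.01
        assert np.all(np.abs(a.params.gamma - b.params.gamma) < 0.01)
        assert np.all(np.abs(a.params.beta - b.params.beta) < 0.01)

    def test_no_events_is_degenerate(self, toy_cohort):
        toy_cohort.survival["status_death"] = 0
        toy_cohort.survival["creatinine"] = [92.0, 130.0]
        cohort = preprocess(toy_cohort, covariates=("creatinine",),
                            constants=TRUTH_SCALING)
        cohort.survival["lvef_scaled"] = cohort.survival["lvef"] / 6.7
        with pytest.raises(DegenerateOutcomeError):
            fit_joint(cohort, "death")

    def test_serialization_roundtrip(self, fit_death150, tmp_path):
        path = tmp_path / "fit.json"
        fit_death150.to_json(path)
        back = JointModelFit.from_json(path)
        np.testing.assert_array_equal(back.theta, fit_death150.theta)
        np.testing.assert_array_equal(back.vcov, fit_death150.vcov)
        assert back.outcome == "death"
        assert back.scaling_constants == fit_death150.scaling_constants
        np.testing.assert_allclose(back.params.beta,
                                   fit_death150.params.beta)


class TestHazardRatioTable:
    def _dummy_fit(self, gamma, alpha):
        params = JointParameters(beta=np.zeros(8), D=np.eye(2), sigma2=1.0,
                                 gamma=np.asarray(gamma, float), alpha=alpha,
                                 baseline=WeibullBaseline(1.0, 1.0))
        theta = np.zeros(21)
        return JointModelFit(params=params, theta=theta,
                             vcov=np.eye(21), loglik=0.0, outcome="death",
                             config=JointConfig(), scaling_constants={},
                             converged=True, n_subjects=0)

    def test_hr_is_exp_of_coefficient(self):
        # death submodel coefficients: AVA -2.61, symptoms 1.87
        fit = self._dummy_fit([-2.61, 0.02, 1.12, 1.87, 0.01, 0.18], 0.5)
        table = fit.hazard_ratio_table().set_index("term")
        assert table.loc["symptoms", "hr"] == 6.49
        assert table.loc["ava", "hr"] == 0.07
        assert table.loc["bnp_current_value", "hr"] == 1.65

    def test_zero_coefficient_gives_unit_hr(self):
        fit = self._dummy_fit(np.zeros(6), 0.0)
        assert (fit.hazard_ratio_table()["hr"] == 1.0).all()


class TestConditionalSurvival:
    COVS = dict(ava=0.74, age=72.0, symptoms=1, male=1, lvef=61.0,
                creatinine=89.0)

    def test_time_zero_is_certain_survival(self, truth):
        s = conditional_survival(truth.params_death, self.COVS,
                                 np.zeros(2), 0.0,
                                 scaling_constants=TRUTH_SCALING)
        assert s == 1.0

    def test_negative_time_rejected(self, truth):
        with pytest.raises(DomainError):
            conditional_survival(truth.params_death, self.COVS,
                                 np.zeros(2), -0.5,
                                 scaling_constants=TRUTH_SCALING)

    def test_severed_link_matches_weibull_closed_form(self, truth):
        p = severed(truth.params_death)
        from bnpjm.joint import subject_design

        w, _ = subject_design(self.COVS, TRUTH_SCALING)
        bl = p.baseline
        for t in (0.3, 1.0, 2.4):
            s = conditional_survival(p, self.COVS, np.array([0.4, -0.1]), t,
                                     scaling_constants=TRUTH_SCALING)
            closed = np.exp(-((t / bl.scale) ** bl.shape)
                            * np.exp(w @ p.gamma))
            assert s == pytest.approx(closed, abs=1e-8)

    def test_survival_is_non_increasing(self, truth):
        grid = np.linspace(0, 3, 100)
        s = [conditional_survival(truth.params_death, self.COVS,
                                  np.array([0.2, 0.1]), t,
                                  scaling_constants=TRUTH_SCALING)
             for t in grid]
        assert np.all(np.diff(s) <= 1e-12)
        assert 0.0 <= s[-1] < 1.0
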