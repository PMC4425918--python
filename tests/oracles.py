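"""Independent reference computations used by the test suite.

These deliberately avoid the package's quadrature code paths: the mixed
model marginal likelihood is computed from stacked multivariate normals,
the proportional-hazards likelihood from the Weibull closed form, and the
joint marginal likelihood by plain Monte-Carlo integration over the random
effects.
"""

import numpy as np
from scipy import stats

from bnpjm.joint import SURV_TERMS, _JointData
from bnpjm.longitudinal import build_design


def lmm_marginal_loglik(params, cohort):
    """Sum of per-subject multivariate-normal log densities."""
    y, X, Z, si, ids = build_design(cohort)
    total = 0.0
    for i in range(len(ids)):
        m = si == i
        if not m.any():
            continue
        V = Z[m] @ params.D @ Z[m].T + params.sigma2 * np.eye(m.sum())
        total += stats.multivariate_normal.logpdf(y[m], X[m] @ params.beta, V)
    return total


def weibull_ph_loglik(params, cohort, outcome):
    """Parametric PH log-likelihood with the trajectory link severed."""
    surv = cohort.survival
    W = surv[list(SURV_TERMS)].to_numpy(float)
    T = surv["obs_time"].to_numpy(float)
    d = surv[f"status_{outcome}"].to_numpy(float)
    eta = W @ params.gamma
    bl = params.baseline
    return float(np.sum(d * (bl.log_h0(T) + eta) - bl.cum_h0(T) * np.exp(eta)))


def mc_joint_loglik(params, cohort, outcome, n_draws=100_000, seed=0):
    """Monte-Carlo integration of the joint likelihood over b, per subject.

    Returns (total_loglik, standard_error_of_total) with the SE propagated
    from each subject's integral by the delta method.
    """
    rng = np.random.default_rng(seed)
    data = _JointData(cohort, outcome)
    L = np.linalg.cholesky(params.D + 1e-12 * np.eye(2))
    total, var_sum = 0.0, 0.0
    for i in range(data.n):
        b = rng.standard_normal((n_draws, 2)) @ L.T
        mask = data.subject_index == i
        ll = np.zeros(n_draws)
        if mask.any():
            yy, tt = data.y[mask], data.t_long[mask]
            mu = data.X[mask] @ params.beta
            resid = yy[None, :] - mu[None, :] - b[:, [0]] - tt[None, :] * b[:, [1]]
            ll += np.sum(-0.5 * np.log(2 * np.pi * params.sigma2)
                         - 0.5 * resid ** 2 / params.sigma2, axis=1)
        m_fix = params.beta[0] + data.base_cov[i] @ params.beta[2:]
        eta = data.W[i] @ params.gamma + params.alpha * (m_fix + b[:, 0])
        c = params.alpha * (params.beta[1] + b[:, 1])
        H = np.exp(eta) * params.baseline.exp_integral(c, data.T[i])
        log_h = params.baseline.log_h0(data.T[i]) + eta + c * data.T[i]
        ll += data.delta[i] * log_h - H
        shift = ll.max()
        w = np.exp(ll - shift)
        mean_w = w.mean()
        total += np.log(mean_w) + shift
        var_sum += (w.std(ddof=1) / np.sqrt(n_draws) / mean_w) ** 2
    return total, float(np.sqrt(var_sum))


def concordance_auc(scores, labels):
    """Brute-force Mann-Whitney AUC over all case-control pairs, ties 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    cases, controls = scores[labels == 1], scores[labels == 0]
    wins = 0.0
    for s1 in cases:
        for s0 in controls:
            wins += 1.0 if s1 > s0 else (0.5 if s1 == s0 else 0.0)
    return wins / (len(cases) * len(controls))
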