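"""Linear mixed-effects submodel for log-BNP evolution.

The biomarker model is

    y_i(t) = x_i(t)'beta + b_i0 + b_i1 * t + eps,   b_i ~ N(0, D),  eps ~ N(0, sigma2)

with fixed effects for time and the baseline covariates (AVA, age, symptoms,
gender, SD-scaled LVEF and SD-scaled creatinine) and a random intercept and
random slope per subject.  Estimation is by maximum likelihood (not REML) so
that the fit can serve as the initializer of the joint likelihood, which is
ML-based.

The actual optimisation is delegated to :class:`statsmodels` ``MixedLM``;
this module owns the design construction, the empirical-Bayes machinery for
new subjects, and the export conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import Cohort
from .errors import ConvergenceError, SchemaError, SingularDesignError

#: fixed-effect terms of the longitudinal submodel, in reporting order
FIXED_TERMS = (
    "intercept",
    "time",
    "ava",
    "age",
    "symptoms",
    "male",
    "lvef_scaled",
    "creatinine_scaled",
)
#: baseline covariates entering the design (everything but intercept/time)
BASELINE_TERMS = FIXED_TERMS[2:]


@dataclass
class MixedModelFit:
    """ML fit of the longitudinal submodel."""

    beta: np.ndarray                 # (8,) fixed effects, FIXED_TERMS order
    D: np.ndarray                    # (2,2) random-effects covariance
    sigma2: float                    # residual variance
    loglik: float
    se_beta: np.ndarray
    blups: pd.DataFrame              # index subject_id, columns intercept/slope
    scaling_constants: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def terms(self):
        return FIXED_TERMS

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table (term, coef, se, p) with two-sided Wald p-values."""
        from scipy import stats

        z = self.beta / self.se_beta
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": FIXED_TERMS, "coef": self.beta, "se": self.se_beta, "p": p}
        )


def _require_preprocessed(cohort: Cohort) -> None:
    if "value_log" not in cohort.longitudinal.columns:
        raise SchemaError("cohort not preprocessed: missing 'value_log' "
                          "(run preprocess first)")
    for col in ("lvef_scaled", "creatinine_scaled"):
        if col not in cohort.survival.columns:
            raise SchemaError(f"cohort not preprocessed: missing {col!r}")


def covariate_row(covariates: dict, scaling_constants: dict) -> np.ndarray:
    """Baseline part of the fixed design for one subject, BASELINE_TERMS order.

    ``covariates`` is on the raw scale (lvef in %, creatinine in micromol/L);
    scaled entries are produced with the stored training SDs.
    """
    row = []
    for term in BASELINE_TERMS:
        if term.endswith("_scaled"):
            raw = term[: -len("_scaled")]
            if raw not in covariates:
                raise SchemaError(f"missing covariate {raw!r}")
            row.append(float(covariates[raw]) / float(scaling_constants[raw]))
        else:
            if term not in covariates:
                raise SchemaError(f"missing covariate {term!r}")
            row.append(float(covariates[term]))
    return np.asarray(row, dtype=float)


def build_design(cohort: Cohort):
    """Stack the longitudinal design: returns (y, X, Z, subject_index, ids)."""
    _require_preprocessed(cohort)
    surv = cohort.survival.set_index("subject_id")
    long_df = cohort.longitudinal
    ids = cohort.survival["subject_id"].to_numpy()
    id_pos = {s: k for k, s in enumerate(ids)}

    y = long_df["value_log"].to_numpy(dtype=float)
    t = long_df["time"].to_numpy(dtype=float)
    cov = surv.loc[long_df["subject_id"], list(BASELINE_TERMS)].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t, cov])
    Z = np.column_stack([np.ones_like(t), t])
    subject_index = long_df["subject_id"].map(id_pos).to_numpy()
    return y, X, Z, subject_index, ids


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved via the QR diagonal
        _, rr = np.linalg.qr(X)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [FIXED_TERMS[j] for j in np.where(diag < tol)[0]]
        raise SingularDesignError(
            f"fixed-effects design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad}", columns=bad,
        )


def fit_lmm(cohort: Cohort) -> MixedModelFit:
    """Maximum-likelihood fit of the mixed model for log-BNP.

    Deterministic given the input: the optimizer path involves no randomness.
    """
    y, X, Z, subject_index, ids = build_design(cohort)
    if len(ids) < 2:
        raise SchemaError("need at least 2 subjects to fit the mixed model")

    if np.ptp(y) == 0.0:
        # degenerate response: every log-value identical; the likelihood is
        # maximized at beta = (const, 0, ...), D = 0, sigma2 -> 0
        beta = np.zeros(X.shape[1])
        beta[0] = y[0]
        return MixedModelFit(
            beta=beta,
            D=np.zeros((2, 2)),
            sigma2=np.finfo(float).tiny,
            loglik=np.inf,
            se_beta=np.zeros(X.shape[1]),
            blups=pd.DataFrame(0.0, index=pd.Index(ids, name="subject_id"),
                               columns=["intercept", "slope"]),
            scaling_constants=dict(cohort.scaling_constants),
        )

    _check_rank(X)
    groups = cohort.longitudinal["subject_id"].to_numpy()
    model = sm.regression.mixed_linear_model.MixedLM(
        y, X, groups=groups, exog_re=Z
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
        if not res.converged:
            res = model.fit(reml=False, method="powell", maxiter=1000)
    if not res.converged:
        raise ConvergenceError(
            "mixed-model fit did not converge",
            diagnostics={"gradient_norm": float(np.max(np.abs(res.score_obs.sum(0))))
                         if hasattr(res, "score_obs") else np.nan},
        )

    beta = np.asarray(res.fe_params, dtype=float)
    D = np.asarray(res.cov_re, dtype=float)
    sigma2 = float(res.scale)
    se_beta = np.asarray(res.bse_fe, dtype=float)

    # statsmodels returns BLUPs keyed by group label
    re = res.random_effects
    blups = pd.DataFrame(
        [np.asarray(re[g], dtype=float) for g in ids],
        index=pd.Index(ids, name="subject_id"),
        columns=["intercept", "slope"],
    )
    return MixedModelFit(
        beta=beta, D=D, sigma2=sigma2, loglik=float(res.llf), se_beta=se_beta,
        blups=blups, scaling_constants=dict(cohort.scaling_constants),
    )


def empirical_bayes(
    beta: np.ndarray, D: np.ndarray, sigma2: float,
    covariate_vec: np.ndarray, times: np.ndarray, values_log: np.ndarray,
) -> np.ndarray:
    """Posterior mean of (b0, b1) for one subject given their measurements.

    Uses b_hat = D Z' (Z D Z' + sigma2 I)^{-1} (y - X beta), which is well
    defined even for singular D; returns the zero vector for an empty history.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(2)
    X = np.column_stack([np.ones_like(times), times,
                         np.tile(covariate_vec, (times.size, 1))])
    Z = np.column_stack([np.ones_like(times), times])
    resid = np.asarray(values_log, dtype=float) - X @ beta
    V = Z @ D @ Z.T + sigma2 * np.eye(times.size)
    return D @ Z.T @ np.linalg.solve(V, resid)


def predict_trajectory(
    fit: MixedModelFit,
    covariates: dict,
    times,
    measurement_times=(),
    measurement_values_log=(),
) -> np.ndarray:
    """Subject-specific mean log-BNP trajectory x(t)'beta + z(t)'b_hat.

    ``covariates`` are raw-scale baseline values; ``measurement_*`` give the
    subject's observed history (log scale) used to shrink toward the subject.
    A subject with no measurements gets the population-mean trajectory.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    cov_vec = covariate_row(covariates, fit.scaling_constants)
    b = empirical_bayes(
        fit.beta, fit.D, fit.sigma2, cov_vec,
        np.asarray(measurement_times, dtype=float),
        np.asarray(measurement_values_log, dtype=float),
    )
    fixed = fit.beta[0] + fit.beta[1] * times + cov_vec @ fit.beta[2:]
    return fixed + b[0] + b[1] * times
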