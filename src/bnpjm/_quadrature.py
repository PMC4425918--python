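"""Quadrature utilities shared by the joint likelihood and the simulator.

Two rules are used:

* a tensor-product Gauss-Hermite grid over the 2-dimensional random effect,
  either in "standard" form (centered at the prior N(0, D)) or "adaptive"
  form (re-centered at a subject-specific Gaussian approximation of the
  posterior, with explicit importance re-weighting);

* a Gauss-Jacobi rule for the Weibull cumulative hazard under a linear
  trajectory, int_0^T s^(k-1) exp(c s) ds.  The weight function t^(k-1)
  absorbs the integrable singularity at 0 exactly, so a modest node count
  gives near machine precision for the smooth exponential factor.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import roots_jacobi

_LOG_PI = float(np.log(np.pi))
#: cap on exponents inside exp() to avoid overflow during optimizer excursions
_EXP_CAP = 700.0


@lru_cache(maxsize=32)
def gh_grid(nodes: int):
    """Tensor 2-D Gauss-Hermite grid.

    Returns ``z`` of shape (Q, 2) and ``logw`` of shape (Q,) such that
    ``int f(b) N(b; 0, D) db ~= sum_q exp(logw_q) f(sqrt(2) L z_q)`` with
    ``L`` the Cholesky factor of D.
    """
    if nodes < 3:
        raise ValueError("need at least 3 quadrature nodes per dimension")
    g, w = hermgauss(nodes)
    z1, z2 = np.meshgrid(g, g, indexing="ij")
    z = np.column_stack([z1.ravel(), z2.ravel()])
    logw = (np.log(w)[:, None] + np.log(w)[None, :]).ravel() - _LOG_PI
    return z, logw


@lru_cache(maxsize=256)
def _jacobi_unit(n: int, k: float):
    """Nodes/weights for int_0^1 t^(k-1) f(t) dt = sum w_j f(t_j)."""
    x, w = roots_jacobi(n, 0.0, k - 1.0)
    # substitution t = (1+x)/2 : weight (1+x)^(k-1) -> (2t)^(k-1), dx = 2 dt
    t = 0.5 * (x + 1.0)
    w = w * 0.5 ** k
    return t, w


def weibull_exp_integral(shape: float, c, T, n_gj: int = 20):
    """``int_0^T k s^(k-1) exp(c s) ds`` (scale folded out by the caller).

    Broadcasts over arrays ``c`` and ``T``; exact for c = 0.
    """
    t, w = _jacobi_unit(n_gj, float(shape))
    c = np.asarray(c, dtype=float)
    T = np.asarray(T, dtype=float)
    expo = np.multiply.outer(c * T, t)  # (..., n_gj) with broadcasting of c*T
    np.clip(expo, None, _EXP_CAP, out=expo)
    s = np.exp(expo) @ w
    return float(shape) * np.power(T, float(shape)) * s


def piecewise_exp_integral(knots, rates, c, T):
    """``int_0^T h0(s) exp(c s) ds`` for a piecewise-constant baseline.

    ``knots`` are the interior+0 cut points (ascending, knots[0] == 0); the
    last piece extends to infinity.  Closed form per piece; stable as c -> 0.
    """
    knots = np.asarray(knots, dtype=float)
    rates = np.asarray(rates, dtype=float)
    c = np.asarray(c, dtype=float)
    T = np.asarray(T, dtype=float)
    cb, Tb = np.broadcast_arrays(c, T)
    out = np.zeros(cb.shape)
    edges = np.append(knots, np.inf)
    for j, rate in enumerate(rates):
        a = np.minimum(Tb, edges[j])
        b = np.minimum(Tb, edges[j + 1])
        width = np.maximum(b - a, 0.0)
        # (exp(c*b) - exp(c*a)) / c  ==  exp(c*a) * expm1(c*width) / c
        small = np.abs(cb) < 1e-12
        with np.errstate(over="ignore", invalid="ignore"):
            term = np.exp(np.clip(cb * a, None, _EXP_CAP)) * np.where(
                small, width, np.expm1(np.clip(cb * width, None, _EXP_CAP))
                / np.where(small, 1.0, cb),
            )
        out += rate * term
    return out


def logsumexp_rows(ll: np.ndarray, logw: np.ndarray) -> np.ndarray:
    """Row-wise log sum_q exp(ll[., q] + logw[., q]) without underflow."""
    a = ll + logw
    amax = np.max(a, axis=-1, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    return (amax + np.log(np.sum(np.exp(a - amax), axis=-1, keepdims=True)))[..., 0]
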