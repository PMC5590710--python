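"""Maximum-likelihood estimation of the MLMM by EM.

The complete-data model treats the subject random-intercept vectors ``b_n``
as missing data.  With ``b_n`` known the model is a multivariate linear
regression, so the M-step is closed form; the E-step needs only the
posterior mean and covariance of ``b_n`` given the data and current
parameters, which is conjugate-normal:

    V_bn  = (Sigma_b^-1 + T_n Sigma_eps^-1)^-1
    b_hat = V_bn Sigma_eps^-1 sum_t (y_nt - mu_nt)

Updates (all from the same E-step posterior):

* fixed effects: per-component least squares of ``y - b_hat`` on the
  covariates (the error weighting cancels because every observed visit
  carries a full component vector);
* Sigma_b  = mean of ``b_hat b_hat' + V_bn`` over subjects;
* Sigma_eps = mean over observed visits of the residual outer products
  ``e e' + V_bn`` with ``e = y - X beta_new - b_hat``.

Each sweep is an ECM step (fixed effects first, covariances given them), so
the marginal log-likelihood is non-decreasing; convergence is declared on
the relative log-likelihood change.  Subjects may skip visits: a skipped
visit is simply an absent row, and subjects are grouped by their observed
visit pattern so every group is processed with dense vectorized algebra.
Partially observed component vectors within a visit are not supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .model import PopulationParams
from .simulate import LongitudinalDataset

__all__ = ["EMFit", "em_fit", "loglikelihood"]

_MODELS = ("time_only", "time_plus_interaction")


@dataclass
class EMFit:
    """EM estimate of the MLMM parameters.

    ``gamma_hat`` is None for the ``time_only`` model.  ``loglik_trace`` is
    non-decreasing up to a 1e-9 numerical slack.
    """

    beta0_hat: np.ndarray
    beta2_hat: np.ndarray
    gamma_hat: Optional[np.ndarray]
    sigma_b_hat: np.ndarray
    sigma_eps_hat: np.ndarray
    loglik_trace: np.ndarray
    iterations: int
    converged: bool
    fixed_effect_se: Optional[np.ndarray] = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_population_params(self, labels=None) -> PopulationParams:
        """Estimates packaged for direct use by the power engine."""
        return PopulationParams(
            beta2=self.beta2_hat,
            sigma_b=self.sigma_b_hat,
            sigma_eps=self.sigma_eps_hat,
            beta0=self.beta0_hat,
            labels=labels,
        )


class _Group:
    """Subjects sharing an observed-visit pattern and arm."""

    def __init__(self, y: np.ndarray, times: np.ndarray, arm: int, model: str):
        self.y = y  # (n, T_g, J)
        self.times = times
        self.arm = arm
        self.n, self.t, self.j = y.shape
        cols = [np.ones_like(times), times]
        if model == "time_plus_interaction":
            cols.append(times * arm)
        self.c = np.column_stack(cols)  # (T_g, p)
        self.y_sum_t = y.sum(axis=1)  # (n, J)

    def mean(self, beta: np.ndarray) -> np.ndarray:
        """Fixed-effect mean per visit, shape (T_g, J); beta is (p, J)."""
        return self.c @ beta


def _split_groups(dataset: LongitudinalDataset, model: str) -> list:
    observed = np.isfinite(dataset.values).all(axis=2)  # (N, T)
    partially = np.isfinite(dataset.values).any(axis=2) & ~observed
    if partially.any():
        raise ValueError(
            "visits with partially observed component vectors are not supported"
        )
    if not observed.any(axis=1).all():
        raise ValueError("every subject needs at least one observed visit")
    groups = {}
    for i in range(dataset.n_subjects):
        key = (tuple(np.flatnonzero(observed[i])), int(dataset.arm[i]))
        groups.setdefault(key, []).append(i)
    out = []
    for (visits, arm), idx in sorted(groups.items()):
        sel = list(visits)
        y = dataset.values[np.ix_(idx, sel)]
        out.append(_Group(y, dataset.times[sel], arm, model))
    return out


def _init_params(groups: list, model: str) -> tuple:
    """Per-component OLS for fixed effects; residual covariance split in half."""
    p = groups[0].c.shape[1]
    j = groups[0].j
    xtx = np.zeros((p, p))
    xty = np.zeros((p, j))
    for g in groups:
        xtx += g.n * g.c.T @ g.c
        xty += g.c.T @ g.y.sum(axis=0)
    beta = np.linalg.solve(xtx, xty)
    ssq = np.zeros((j, j))
    count = 0
    for g in groups:
        resid = g.y - g.mean(beta)[None]
        ssq += np.einsum("nti,ntj->ij", resid, resid)
        count += g.n * g.t
    pooled = ssq / count
    half = 0.5 * pooled
    return beta, half + 1e-8 * np.eye(j), half + 1e-8 * np.eye(j)


def _safe_chol(a: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        warnings.warn(f"{name} update not positive definite; applying 1e-10 ridge")
        return np.linalg.cholesky(a + 1e-10 * np.eye(a.shape[0]))


def _group_loglik(g: _Group, beta, sigma_b, sigma_eps) -> float:
    """Marginal MVN log-density of one pattern group, all subjects at once."""
    t, j = g.t, g.j
    v = np.kron(np.eye(t), sigma_eps) + np.kron(np.ones((t, t)), sigma_b)
    chol = _safe_chol(v, "marginal covariance")
    resid = (g.y - g.mean(beta)[None]).reshape(g.n, t * j)
    sol = solve_triangular(chol, resid.T, lower=True)
    quad = float(np.sum(sol**2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (g.n * (t * j * np.log(2 * np.pi) + logdet) + quad)


def loglikelihood(
    dataset: LongitudinalDataset,
    params: PopulationParams,
    beta: Optional[np.ndarray] = None,
    model: str = "time_plus_interaction",
) -> float:
    """Marginal MLMM log-likelihood at given parameters.

    ``beta`` is the (p, J) fixed-effect matrix with rows (beta0, beta2[,
    gamma]); if omitted it is assembled from ``params`` (gamma = 0 for
    ``time_only``).
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    groups = _split_groups(dataset, model)
    if beta is None:
        rows = [params.beta0, params.beta2]
        if model == "time_plus_interaction":
            rows.append(np.zeros(params.n_components))
        beta = np.vstack(rows)
    total = 0.0
    for g in groups:
        total += _group_loglik(g, beta, params.sigma_b, params.sigma_eps)
    return float(total)


def em_fit(
    dataset: LongitudinalDataset,
    model: str = "time_only",
    init: Optional[tuple] = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> EMFit:
    """Fit the MLMM by EM.

    Parameters
    ----------
    dataset
        Longitudinal records; subjects may skip visits.
    model
        ``time_only`` (observational: intercept + slope) or
        ``time_plus_interaction`` (adds the treatment-by-time effect).
    init
        Optional ``(beta, sigma_b, sigma_eps)`` starting point with ``beta``
        of shape (p, J); default is per-component OLS with the pooled
        residual covariance split evenly between the two matrices.
    max_iter, tol
        Iteration cap and relative log-likelihood convergence tolerance.  On
        hitting the cap the fit is returned with ``converged=False``.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    groups = _split_groups(dataset, model)
    j = groups[0].j
    n_total = sum(g.n for g in groups)
    obs_visits = sum(g.n * g.t for g in groups)
    if init is not None:
        beta, sigma_b, sigma_eps = init
        beta = np.asarray(beta, dtype=float)
        sigma_b = np.asarray(sigma_b, dtype=float)
        sigma_eps = np.asarray(sigma_eps, dtype=float)
    else:
        beta, sigma_b, sigma_eps = _init_params(groups, model)

    trace = [sum(_group_loglik(g, beta, sigma_b, sigma_eps) for g in groups)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        se_inv = np.linalg.inv(sigma_eps)
        sb_inv = np.linalg.inv(sigma_b + 1e-300 * np.eye(j))
        # E-step: posterior moments of b_n per pattern group
        posts = []
        for g in groups:
            v_b = np.linalg.inv(sb_inv + g.t * se_inv)
            resid_sum = g.y_sum_t - (g.mean(beta).sum(axis=0))[None]  # (n, J)
            b_hat = resid_sum @ (v_b @ se_inv).T
            posts.append((v_b, b_hat))
        # M-step 1: fixed effects from de-intercepted responses
        p = groups[0].c.shape[1]
        xtx = np.zeros((p, p))
        xty = np.zeros((p, j))
        for g, (v_b, b_hat) in zip(groups, posts):
            xtx += g.n * g.c.T @ g.c
            adj = g.y - b_hat[:, None, :]
            xty += g.c.T @ adj.sum(axis=0)
        beta = np.linalg.solve(xtx, xty)
        # M-step 2: covariance updates from posterior moments
        s_b = np.zeros((j, j))
        s_e = np.zeros((j, j))
        for g, (v_b, b_hat) in zip(groups, posts):
            s_b += b_hat.T @ b_hat + g.n * v_b
            e = g.y - g.mean(beta)[None] - b_hat[:, None, :]
            s_e += np.einsum("nti,ntj->ij", e, e) + g.n * g.t * v_b
        sigma_b = 0.5 * (s_b + s_b.T) / n_total
        sigma_eps = 0.5 * (s_e + s_e.T) / obs_visits
        _safe_chol(sigma_eps, "sigma_eps")
        ll = sum(_group_loglik(g, beta, sigma_b, sigma_eps) for g in groups)
        trace.append(ll)
        if ll + 1e-9 * (abs(ll) + 1.0) < trace[-2]:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{trace[-2]:.10g} -> {ll:.10g}"
            )
        if abs(ll - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    se = _fixed_effect_se(groups, sigma_b, sigma_eps)
    gamma_hat = beta[2] if model == "time_plus_interaction" else None
    return EMFit(
        beta0_hat=beta[0],
        beta2_hat=beta[1],
        gamma_hat=gamma_hat,
        sigma_b_hat=sigma_b,
        sigma_eps_hat=sigma_eps,
        loglik_trace=np.array(trace),
        iterations=it,
        converged=converged,
        fixed_effect_se=se,
    )


def _fixed_effect_se(groups: list, sigma_b, sigma_eps) -> np.ndarray:
    """Asymptotic SEs of the fixed effects at the fitted covariances.

    Based on the known-covariance Fisher information sum_n X_n' V_n^-1 X_n;
    returned as a (p, J) array matching the beta layout.
    """
    j = groups[0].j
    p = groups[0].c.shape[1]
    info = np.zeros((p * j, p * j))
    for g in groups:
        v = np.kron(np.eye(g.t), sigma_eps) + np.kron(np.ones((g.t, g.t)), sigma_b)
        x = np.kron(g.c, np.eye(j))
        info += g.n * x.T @ np.linalg.solve(v, x)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    return np.sqrt(np.diag(cov)).reshape(p, j)
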