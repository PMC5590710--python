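"""Composite-weight strategies: equal, unit, and power-optimal vectors.

Two data-driven optima are provided, both normalized to the unit sphere and
signed so that ``w'gamma+ > 0`` against the positive rate-reduction
magnitudes:

* ``w_JC*`` maximizes the power of the weighted-effect statistic Xi_JC(w).
  The maximizer of the Rayleigh quotient (w'gamma*)^2 / (w'Sigma_gamma1 w)
  is closed form: w proportional to Sigma_gamma1^-1 gamma*, the leading
  eigenvector of Sigma_gamma1^-1 gamma* gamma*'.  At the optimum the
  quotient equals gamma*' Sigma_gamma1^-1 gamma*, the full joint-test
  noncentrality — so Xi_JC(w_JC*) carries the same noncentrality as Xi_J on
  a single degree of freedom.
* ``w_C*`` maximizes the power of the composite-score statistic Xi_C(w),
  i.e. (w'gamma*)^2 / sigma_gamma1^2(w).  The denominator involves the
  composite-LMM information rather than a quadratic form, so the optimum is
  found numerically: the sphere constraint is removed by normalizing inside
  the objective, and a quasi-Newton search is run from multiple starts
  (equal weights, w_JC*, each unit vector, and random directions under a
  fixed seed), keeping the best converged local maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (
    EffectSpec,
    PopulationParams,
    TrialDesign,
    WeightVector,
    composite_gamma_variance_unit,
    gamma_covariance_unit,
)

__all__ = [
    "equal_weights",
    "unit_weight",
    "optimal_weights_jc",
    "optimal_weights_c",
    "weight_table",
]

_MULTISTART_SEED = 20170524


def equal_weights(n_components: int) -> WeightVector:
    """All entries J^{-1/2}: the naive benchmark composite."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    return WeightVector(np.ones(n_components), strategy="equal")


def unit_weight(n_components: int, component: int) -> WeightVector:
    """Weight entirely on one component (0-based index)."""
    if not 0 <= component < n_components:
        raise ValueError("component index out of range")
    return WeightVector(np.eye(n_components)[component], strategy="unit_j")


def optimal_weights_jc(
    gamma_star: np.ndarray, sigma_gamma1: np.ndarray
) -> WeightVector:
    """Closed-form optimum for Xi_JC: w proportional to Sigma_gamma1^-1 gamma*."""
    g = np.atleast_1d(np.asarray(gamma_star, dtype=float))
    if not np.any(g):
        raise ValueError("gamma_star must be nonzero")
    direction = np.linalg.solve(sigma_gamma1, g)
    return WeightVector(direction, strategy="optimal_jc").oriented(np.abs(g))


def _c_objective(
    params: PopulationParams, design: TrialDesign, g: np.ndarray
):
    def objective(v: np.ndarray) -> float:
        w = v / np.linalg.norm(v)
        comp = composite_gamma_variance_unit(w, params, design)
        return -float(w @ g) ** 2 / comp.sigma_gamma1_sq

    return objective


def _projected_gradient_norm(objective, v: np.ndarray, h: float = 1e-6) -> float:
    """Norm of the numerical gradient projected on the sphere's tangent space."""
    w = v / np.linalg.norm(v)
    grad = np.empty_like(w)
    for i in range(w.size):
        e = np.zeros_like(w)
        e[i] = h
        grad[i] = (objective(w + e) - objective(w - e)) / (2 * h)
    tangent = grad - (grad @ w) * w
    return float(np.linalg.norm(tangent))


def optimal_weights_c(
    gamma_star: np.ndarray,
    params: PopulationParams,
    design: TrialDesign,
    n_random_starts: int = 32,
    seed: int = _MULTISTART_SEED,
) -> WeightVector:
    """Numerical optimum for Xi_C: maximize (w'gamma*)^2 / sigma_gamma1^2(w).

    Multi-start BFGS with the normalization folded into the objective; the
    best local maximum with projected-gradient norm below 1e-8 (relative to
    the objective scale) is returned.
    """
    g = np.atleast_1d(np.asarray(gamma_star, dtype=float))
    if not np.any(g):
        raise ValueError("gamma_star must be nonzero")
    j = params.n_components
    if g.size != j:
        raise ValueError("gamma_star dimension does not match params")
    objective = _c_objective(params, design, g)
    sg1 = gamma_covariance_unit(params, design).sigma_gamma1
    starts = [np.ones(j) / np.sqrt(j), optimal_weights_jc(g, sg1).w]
    starts.extend(np.eye(j))
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(rng.standard_normal(j))
    best = None
    diagnostics = []
    for start in starts:
        res = optimize.minimize(
            objective, start, method="BFGS", options={"gtol": 1e-12, "maxiter": 500}
        )
        scale = max(1.0, abs(res.fun))
        pgrad = _projected_gradient_norm(objective, res.x)
        diagnostics.append((res.fun, pgrad))
        if pgrad > 1e-8 * scale:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "optimal_weights_c failed to converge from any start; "
            f"(objective, projected gradient) per start: {diagnostics}"
        )
    return WeightVector(best.x, strategy="optimal_c").oriented(np.abs(g))


def weight_table(
    params: PopulationParams,
    effect: EffectSpec,
    durations: Sequence[float] = (2, 3, 4, 5, 6),
    base_design: Optional[TrialDesign] = None,
) -> pd.DataFrame:
    """Optimal weights w_JC* and w_C* per trial duration.

    Rows are (weight set, component), columns the durations in years.
    """
    base = base_design if base_design is not None else TrialDesign(duration_years=2)
    rows = {}
    for dur in durations:
        design = base.with_duration(float(dur))
        g = effect.gamma_for(params)
        sg1 = gamma_covariance_unit(params, design).sigma_gamma1
        wjc = optimal_weights_jc(g, sg1)
        wc = optimal_weights_c(g, params, design)
        rows[dur] = np.concatenate([wjc.w, wc.w])
    index = pd.MultiIndex.from_tuples(
        [("w_JC*", lab) for lab in params.labels]
        + [("w_C*", lab) for lab in params.labels],
        names=["weights", "component"],
    )
    table = pd.DataFrame(rows, index=index)
    table.columns = [f"{float(d):g}y" for d in durations]
    return table
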