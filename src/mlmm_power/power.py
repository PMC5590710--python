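"""Noncentral-chi-square power and analytic sample-size solving.

Three Wald statistics test for a treatment effect on the component rates:

* ``Xi_J   = gamma_hat' Sigma_gamma^-1 gamma_hat`` — joint test of all J
  component effects (chi-square, df = J);
* ``Xi_JC(w) = (w' gamma_hat)^2 / (w' Sigma_gamma w)`` — test of the weighted
  combination of effects estimated under the multivariate model (df = 1);
* ``Xi_C(w)  = gamma_hat_w^2 / sigma_gamma^2`` — test of the treatment effect
  in the univariate LMM fitted to the composite score w'Y (df = 1).

Under the alternative each statistic is noncentral chi-square with
noncentrality ``lambda = N * lambda1``, where the per-participant
noncentrality ``lambda1`` depends on the statistic:

    lambda1(J)     = gamma*' Sigma_gamma1^-1 gamma*
    lambda1(JC, w) = (w' gamma*)^2 / (w' Sigma_gamma1 w)
    lambda1(C, w)  = (w' gamma*)^2 / sigma_gamma1^2(w)

The required total sample size is ``N = ceil(lambda_req / lambda1)`` with
``lambda_req`` the noncentrality at which the noncentral chi-square test
attains the target power.  One-sided Z versions of the df-1 statistics use
the signed square root and the normal-quantile requirement
``(z_{1-alpha} + z_{power})^2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .model import (
    CompositeVariance,
    EffectSpec,
    GammaCovariance,
    PopulationParams,
    TrialDesign,
    WeightVector,
    composite_gamma_variance_unit,
    gamma_covariance_unit,
)

__all__ = [
    "PowerRequest",
    "PowerResult",
    "BonferroniResult",
    "chi2_power",
    "one_sided_z_power",
    "required_noncentrality",
    "required_noncentrality_one_sided",
    "noncentrality_per_participant",
    "sample_size",
    "power_at_n",
    "bonferroni_sample_size",
]

_STATISTICS = ("J", "JC", "C")


@dataclass(frozen=True)
class PowerRequest:
    """Which Wald statistic to power, with test settings.

    ``weights`` are required for the df-1 statistics JC and C and ignored for
    the joint statistic J.
    """

    statistic: str
    weights: Optional[WeightVector] = None
    alpha: float = 0.05
    target_power: float = 0.80
    sidedness: str = "two_sided_chi2"

    def __post_init__(self):
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {_STATISTICS}")
        if self.statistic in ("JC", "C") and self.weights is None:
            raise ValueError(f"statistic {self.statistic} requires weights")
        if self.sidedness not in ("two_sided_chi2", "one_sided_z"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.sidedness == "one_sided_z" and self.statistic == "J":
            raise ValueError(
                "one-sided testing is only supported for the df-1 statistics JC and C"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Analytic power-analysis output for one statistic/weight choice."""

    statistic: str
    weights: Optional[WeightVector]
    df: int
    lambda1: float
    lambda_req: float
    n_required: int
    sidedness: str = "two_sided_chi2"

    @property
    def n_per_arm(self) -> int:
        """Per-arm size for display (equal allocation, rounded up)."""
        return math.ceil(self.n_required / 2)


@dataclass(frozen=True)
class BonferroniResult:
    """Per-component powering at alpha/J; the trial takes the maximum N."""

    n_required: int
    per_component: tuple


def chi2_power(df: int, lam: float, alpha: float) -> float:
    """Power of the level-alpha chi-square(df) test at noncentrality lam."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if lam < 0:
        raise ValueError("noncentrality must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))


def one_sided_z_power(lam: float, alpha: float) -> float:
    """Power of the one-sided level-alpha Z test at mean shift sqrt(lam).

    The shift is taken in the beneficial (rejection) direction.
    """
    if lam < 0:
        raise ValueError("noncentrality must be >= 0")
    return float(stats.norm.sf(stats.norm.ppf(1.0 - alpha) - math.sqrt(lam)))


def required_noncentrality(df: int, alpha: float, target_power: float) -> float:
    """Noncentrality at which the chi-square(df) test reaches target power.

    Solved by bracketed root-finding on [0, 1e4]; for df = 1 this equals the
    normal-approximation identity (z_{1-alpha/2} + z_{power})^2.
    """
    if target_power <= alpha:
        raise ValueError("target_power must exceed alpha")
    crit = stats.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - target_power

    return float(optimize.brentq(gap, 0.0, 1e4, xtol=1e-10, rtol=8.9e-16))


def required_noncentrality_one_sided(alpha: float, target_power: float) -> float:
    """One-sided Z requirement (z_{1-alpha} + z_{power})^2."""
    if target_power < alpha:
        raise ValueError("target_power must be at least alpha")
    return float((stats.norm.ppf(1.0 - alpha) + stats.norm.ppf(target_power)) ** 2)


def noncentrality_per_participant(
    request: PowerRequest,
    gamma_star: np.ndarray,
    gamma_cov: GammaCovariance,
    composite: Optional[CompositeVariance] = None,
) -> float:
    """Per-participant noncentrality lambda1 of the requested statistic.

    lambda at total size N is N * lambda1.  Invariant to rescaling the
    weights.  A weight vector orthogonal to gamma* yields lambda1 = 0 (the
    effect is undetectable by that composite; power never exceeds alpha).
    """
    g = np.atleast_1d(np.asarray(gamma_star, dtype=float))
    sg1 = gamma_cov.sigma_gamma1
    if g.size != sg1.shape[0]:
        raise ValueError("gamma_star dimension does not match Sigma_gamma1")
    if request.statistic == "J":
        return float(g @ np.linalg.solve(sg1, g))
    w = request.weights.w
    if w.size != g.size:
        raise ValueError("weight dimension does not match gamma_star")
    num = float(w @ g) ** 2
    if request.statistic == "JC":
        den = float(w @ sg1 @ w)
    else:
        if composite is None:
            raise ValueError("statistic C requires the composite variance")
        den = composite.sigma_gamma1_sq
    if den <= 0:
        raise ValueError("noncentrality denominator must be positive")
    lam1 = num / den
    if lam1 == 0.0:
        warnings.warn(
            "weights are orthogonal to the treatment effect: lambda1 = 0, "
            "power cannot exceed alpha",
            stacklevel=2,
        )
    return lam1


def _lambda1_for(
    request: PowerRequest,
    params: PopulationParams,
    effect: EffectSpec,
    design: TrialDesign,
) -> tuple:
    gamma_cov = gamma_covariance_unit(params, design)
    composite = None
    if request.statistic == "C":
        composite = composite_gamma_variance_unit(request.weights, params, design)
    g = effect.gamma_for(params)
    lam1 = noncentrality_per_participant(request, g, gamma_cov, composite)
    df = params.n_components if request.statistic == "J" else 1
    return lam1, df


def sample_size(
    request: PowerRequest,
    params: PopulationParams,
    effect: EffectSpec,
    design: TrialDesign,
) -> PowerResult:
    """Smallest total N whose analytic power reaches the target.

    N = ceil(lambda_req / lambda1); the continuous solution is rounded up
    (not to an even total).
    """
    lam1, df = _lambda1_for(request, params, effect, design)
    if lam1 <= 0:
        raise ValueError(
            "treatment effect is undetectable by the requested statistic (lambda1 = 0)"
        )
    if request.sidedness == "one_sided_z":
        lam_req = required_noncentrality_one_sided(request.alpha, request.target_power)
    else:
        lam_req = required_noncentrality(df, request.alpha, request.target_power)
    n = math.ceil(lam_req / lam1 - 1e-12)
    n = max(n, 2)
    return PowerResult(
        statistic=request.statistic,
        weights=request.weights,
        df=df,
        lambda1=lam1,
        lambda_req=lam_req,
        n_required=n,
        sidedness=request.sidedness,
    )


def power_at_n(
    request: PowerRequest,
    params: PopulationParams,
    effect: EffectSpec,
    design: TrialDesign,
    n_total: float,
) -> float:
    """Analytic power of the requested test at total sample size N."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    lam1, df = _lambda1_for(request, params, effect, design)
    if request.sidedness == "one_sided_z":
        return one_sided_z_power(n_total * lam1, request.alpha)
    return chi2_power(df, n_total * lam1, request.alpha)


def bonferroni_sample_size(
    params: PopulationParams,
    effect: EffectSpec,
    design: TrialDesign,
    alpha: Optional[float] = None,
    target_power: Optional[float] = None,
) -> BonferroniResult:
    """Power each component separately at level alpha/J; take the largest N.

    Each component is powered with the composite-score statistic Xi_C at the
    unit weight selecting that component, i.e. a univariate LMM per endpoint
    with a Bonferroni-corrected significance level.
    """
    alpha = design.alpha if alpha is None else alpha
    target_power = design.target_power if target_power is None else target_power
    j = params.n_components
    per = []
    for comp in range(j):
        w = WeightVector(np.eye(j)[comp], strategy="unit_j")
        req = PowerRequest(
            statistic="C", weights=w, alpha=alpha / j, target_power=target_power
        )
        per.append(sample_size(req, params, effect, design))
    return BonferroniResult(
        n_required=max(r.n_required for r in per), per_component=tuple(per)
    )
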