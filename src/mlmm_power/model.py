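"""Design mathematics for the multivariate linear mixed-effects model (MLMM).

The model for the *j*-th of ``J`` longitudinal component scores of
participant *n* at visit time *t* (years) is

    Y_ntj = beta0_j + (beta2_j + gamma_j * arm_n) * t + b_nj + eps_ntj,

where ``arm_n`` is 1 for treated and 0 for control, the random intercepts
``b_n = (b_n1, ..., b_nJ)`` are MVN(0, Sigma_b), and the visit-level errors
``eps_nt`` are MVN(0, Sigma_eps), independent across visits and of ``b_n``.
The treatment effect ``gamma_j`` acts on the annual rate of change; it is the
coefficient of the treatment-by-time interaction and the quantity a trial is
powered to detect.

A composite score ``C_nt = w' Y_nt`` then follows a univariate linear mixed
model of the same form with variance components ``sigma_a^2 = w' Sigma_b w``
(random intercept) and ``sigma_d^2 = w' Sigma_eps w`` (error), so the whole
machinery below applies unchanged at J = 1.

All information/covariance computations treat the covariance matrices as
known, which yields closed-form generalized-least-squares estimators and an
exact per-participant Fisher information.

Conventions (fixed so serialized matrices are comparable):

* observations are stacked visit-major — visit outer loop, component inner;
* fixed effects are ordered (all beta0_j, all beta2_j, all gamma_j);
* a d-year design with visit spacing Δ schedules T = d/Δ visits at
  0, Δ, ..., d − Δ (so the 2-year biannual design has four visits);
* reported sample sizes are totals across both arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PopulationParams",
    "EffectSpec",
    "TrialDesign",
    "GammaCovariance",
    "CompositeVariance",
    "WeightVector",
    "build_subject_design",
    "marginal_covariance",
    "per_participant_information",
    "gamma_covariance_unit",
    "composite_variance_components",
    "composite_population",
    "composite_gamma_variance_unit",
]


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=tol, rtol=tol):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (a + a.T)


def _check_psd(a: np.ndarray, name: str, strict: bool = False) -> None:
    eig = np.linalg.eigvalsh(a)
    scale = float(np.abs(eig).max())
    if strict:
        if eig.min() <= 0 or eig.min() < 1e-13 * scale:
            raise ValueError(f"{name} must be positive definite (min eigenvalue {eig.min():.3g})")
    elif eig.min() < -1e-12 * max(1.0, scale):
        raise ValueError(f"{name} must be positive semi-definite (min eigenvalue {eig.min():.3g})")


@dataclass(frozen=True)
class PopulationParams:
    """Population parameters of the MLMM.

    Parameters
    ----------
    beta2
        Length-J vector of annual rates of change (score units / year).
    sigma_b
        J×J covariance of the subject random intercepts (PSD).
    sigma_eps
        J×J covariance of the visit-level errors (PD).
    beta0
        Length-J intercepts; default zero.  Intercepts do not enter the
        treatment-effect information, so power results are invariant to them.
    labels
        Component names, for table output.
    """

    beta2: np.ndarray
    sigma_b: np.ndarray
    sigma_eps: np.ndarray
    beta0: Optional[np.ndarray] = None
    labels: Optional[tuple] = None

    def __post_init__(self):
        beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        if beta2.ndim != 1 or not np.all(np.isfinite(beta2)):
            raise ValueError("beta2 must be a finite 1-d vector")
        j = beta2.size
        sb = _check_symmetric(self.sigma_b, "sigma_b")
        se = _check_symmetric(self.sigma_eps, "sigma_eps")
        if sb.shape != (j, j) or se.shape != (j, j):
            raise ValueError("sigma_b and sigma_eps must be J x J with J = len(beta2)")
        _check_psd(sb, "sigma_b")
        _check_psd(se, "sigma_eps", strict=True)
        beta0 = self.beta0
        beta0 = np.zeros(j) if beta0 is None else np.atleast_1d(np.asarray(beta0, dtype=float))
        if beta0.shape != (j,):
            raise ValueError("beta0 must have the same length as beta2")
        labels = self.labels
        if labels is None:
            labels = tuple(f"y{i + 1}" for i in range(j))
        labels = tuple(str(x) for x in labels)
        if len(labels) != j:
            raise ValueError("labels must have one entry per component")
        object.__setattr__(self, "beta2", beta2)
        object.__setattr__(self, "sigma_b", sb)
        object.__setattr__(self, "sigma_eps", se)
        object.__setattr__(self, "beta0", beta0)
        object.__setattr__(self, "labels", labels)

    @property
    def n_components(self) -> int:
        return self.beta2.size


@dataclass(frozen=True)
class EffectSpec:
    """Alternative-hypothesis treatment effect.

    In ``fraction_of_rate`` mode the treatment slows each component's annual
    rate of change by ``reduction_fraction`` (default 25%), i.e.
    ``gamma*_j = -reduction_fraction * beta2_j``.  ``explicit`` mode carries
    an arbitrary finite effect vector.
    """

    mode: str = "fraction_of_rate"
    reduction_fraction: float = 0.25
    gamma_star: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in ("fraction_of_rate", "explicit"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if self.mode == "fraction_of_rate":
            if not 0.0 < self.reduction_fraction <= 1.0:
                raise ValueError("reduction_fraction must be in (0, 1]")
        else:
            if self.gamma_star is None:
                raise ValueError("explicit mode requires gamma_star")
            g = np.atleast_1d(np.asarray(self.gamma_star, dtype=float))
            if not np.all(np.isfinite(g)):
                raise ValueError("gamma_star must be finite")
            object.__setattr__(self, "gamma_star", g)

    def gamma_for(self, params: PopulationParams) -> np.ndarray:
        """Signed treatment-effect vector under the alternative."""
        if self.mode == "fraction_of_rate":
            return -self.reduction_fraction * params.beta2
        g = self.gamma_star
        if g.size != params.n_components:
            raise ValueError("gamma_star dimension does not match params")
        return g

    def magnitude_for(self, params: PopulationParams) -> np.ndarray:
        """Positive rate-reduction magnitudes |gamma*| (weight orientation)."""
        return np.abs(self.gamma_for(params))


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm trial layout: visit grid, allocation and test settings.

    A ``duration_years`` trial with ``visit_interval_years`` spacing schedules
    ``T = duration/interval`` visits at 0, Δ, ..., duration − Δ.  ``allocation``
    is the treated fraction.
    """

    duration_years: float
    visit_interval_years: float = 0.5
    allocation: float = 0.5
    alpha: float = 0.05
    target_power: float = 0.80
    sidedness: str = "two_sided_chi2"

    def __post_init__(self):
        if self.duration_years <= 0 or self.visit_interval_years <= 0:
            raise ValueError("duration and visit interval must be positive")
        ratio = self.duration_years / self.visit_interval_years
        if abs(ratio - round(ratio)) > 1e-8:
            raise ValueError("duration_years must be an integer multiple of visit_interval_years")
        if round(ratio) < 2:
            raise ValueError("need at least two visits to identify a slope")
        if not 0.0 < self.allocation < 1.0:
            raise ValueError("allocation must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")
        if self.sidedness not in ("two_sided_chi2", "one_sided_z"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")

    @property
    def n_visits(self) -> int:
        return int(round(self.duration_years / self.visit_interval_years))

    @property
    def visit_times(self) -> np.ndarray:
        return np.arange(self.n_visits) * self.visit_interval_years

    def with_duration(self, duration_years: float) -> "TrialDesign":
        return replace(self, duration_years=duration_years)


@dataclass(frozen=True)
class GammaCovariance:
    """Per-participant-scaled covariance of the treatment-effect estimator.

    ``Cov(gamma_hat) = sigma_gamma1 / N`` at total sample size N.
    """

    sigma_gamma1: np.ndarray
    design: TrialDesign

    def cov_at(self, n_total: float) -> np.ndarray:
        if n_total <= 0:
            raise ValueError("n_total must be positive")
        return self.sigma_gamma1 / n_total


@dataclass(frozen=True)
class CompositeVariance:
    """Variance components of the composite-score LMM induced by weights w.

    sigma_a2 = w' Sigma_b w, sigma_d2 = w' Sigma_eps w, and
    Var(gamma_hat_w) = sigma_gamma1_sq / N for the composite-score fit.
    """

    sigma_a2: float
    sigma_d2: float
    sigma_gamma1_sq: float


@dataclass(frozen=True)
class WeightVector:
    """L2-normalized composite weights.

    The stored vector always satisfies ``sum(w_j^2) == 1``.  Use
    :meth:`oriented` to fix the sign convention ``w'gamma+ > 0`` against the
    positive rate-reduction magnitudes.
    """

    w: np.ndarray
    strategy: str = "custom"

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        norm = float(np.linalg.norm(w))
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("weight vector must be finite and nonzero")
        object.__setattr__(self, "w", w / norm)

    def oriented(self, direction: np.ndarray) -> "WeightVector":
        """Return a copy signed so that ``w @ direction > 0``."""
        if float(self.w @ np.asarray(direction, dtype=float)) < 0.0:
            return WeightVector(-self.w, self.strategy)
        return self

    @property
    def size(self) -> int:
        return self.w.size


def build_subject_design(
    design: TrialDesign, params: PopulationParams, arm: int
) -> np.ndarray:
    """Fixed-effect design matrix for one subject (J·T rows, 3J columns).

    Rows are visit-major; columns are (beta0_j, beta2_j, gamma_j) blocks.  The
    treatment-by-time interaction column holds the visit time for a treated
    subject and zero for control.
    """
    if arm not in (0, 1):
        raise ValueError("arm must be 0 (control) or 1 (treated)")
    j = params.n_components
    times = design.visit_times
    eye = np.eye(j)
    blocks = [np.hstack([eye, t * eye, (t * arm) * eye]) for t in times]
    return np.vstack(blocks)


def marginal_covariance(params: PopulationParams, n_visits: int) -> np.ndarray:
    """Marginal covariance V of one subject's stacked J·T observation vector.

    Under visit-major ordering V = I_T ⊗ Sigma_eps + 1_T 1_T' ⊗ Sigma_b:
    diagonal J×J blocks are Sigma_eps + Sigma_b, off-diagonal blocks Sigma_b.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    t = int(n_visits)
    return np.kron(np.eye(t), params.sigma_eps) + np.kron(
        np.ones((t, t)), params.sigma_b
    )


def per_participant_information(
    params: PopulationParams, design: TrialDesign
) -> np.ndarray:
    """Expected (averaged over arms) per-participant Fisher information.

    I_bar = allocation * X_t' V^-1 X_t + (1-allocation) * X_c' V^-1 X_c, the
    information about (beta0, beta2, gamma) contributed by one participant
    under known covariance matrices.  Total information at size N is N·I_bar.
    """
    v = marginal_covariance(params, design.n_visits)
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by PD checks
        raise np.linalg.LinAlgError(
            "marginal covariance V is singular; check sigma_eps"
        ) from exc
    xc = build_subject_design(design, params, arm=0)
    xt = build_subject_design(design, params, arm=1)
    pi = design.allocation
    info = pi * xt.T @ vinv @ xt + (1.0 - pi) * xc.T @ vinv @ xc
    return 0.5 * (info + info.T)


def gamma_covariance_unit(
    params: PopulationParams, design: TrialDesign
) -> GammaCovariance:
    """Per-participant-scaled covariance Sigma_gamma1 of gamma_hat.

    The gamma×gamma block of the inverse averaged information; the covariance
    of the GLS treatment-effect estimator at total size N is Sigma_gamma1/N.
    """
    if design.n_visits < 2:
        raise ValueError("at least two visits are required to identify the slope")
    j = params.n_components
    info = per_participant_information(params, design)
    try:
        inv = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "per-participant information matrix is singular"
        ) from exc
    sg1 = inv[2 * j :, 2 * j :]
    return GammaCovariance(0.5 * (sg1 + sg1.T), design)


def composite_variance_components(
    w: WeightVector | np.ndarray, params: PopulationParams
) -> tuple:
    """Quadratic forms (sigma_a2, sigma_d2) = (w'Sigma_b w, w'Sigma_eps w).

    No normalization is applied internally: a raw vector is used as given.
    """
    wv = w.w if isinstance(w, WeightVector) else np.atleast_1d(np.asarray(w, dtype=float))
    if wv.size != params.n_components:
        raise ValueError("weight dimension does not match number of components")
    return float(wv @ params.sigma_b @ wv), float(wv @ params.sigma_eps @ wv)


def composite_population(
    w: WeightVector | np.ndarray, params: PopulationParams, label: str = "composite"
) -> PopulationParams:
    """Univariate population induced by the composite score C = w'Y."""
    wv = w.w if isinstance(w, WeightVector) else np.atleast_1d(np.asarray(w, dtype=float))
    sa2, sd2 = composite_variance_components(wv, params)
    if sd2 <= 0:
        raise ValueError("composite error variance w'Sigma_eps w must be positive")
    return PopulationParams(
        beta2=np.array([float(wv @ params.beta2)]),
        sigma_b=np.array([[sa2]]),
        sigma_eps=np.array([[sd2]]),
        beta0=np.array([float(wv @ params.beta0)]),
        labels=(label,),
    )


def _univariate_gamma_variance(
    sd2: float, sa2: float, times: np.ndarray, allocation: float
) -> float:
    """J = 1 per-participant gamma variance via the rank-one V inverse.

    V = sd2*I + sa2*11' has inverse (1/sd2)(I - (sa2/(sd2 + T sa2)) 11'),
    so the 3x3 per-arm information reduces to inner products of the columns
    (1, t, arm*t); identical to the generic path, just closed form.
    """
    t = np.asarray(times, dtype=float)
    n_vis = t.size
    st = float(t.sum())
    stt = float(t @ t)
    alpha = 1.0 / sd2
    beta = sa2 / (sd2 * (sd2 + n_vis * sa2))
    q11 = alpha * n_vis - beta * n_vis * n_vis
    q1t = alpha * st - beta * n_vis * st
    qtt = alpha * stt - beta * st * st
    pi = allocation
    # information [[q11, q1t, pi q1t], [q1t, qtt, pi qtt], [pi q1t, pi qtt, pi qtt]];
    # gamma variance via the Schur complement of the (beta0, beta2) block
    det = q11 * qtt - q1t * q1t
    if det <= 0 or qtt <= 0:
        raise np.linalg.LinAlgError("univariate information matrix is singular")
    b1, b2 = pi * q1t, pi * qtt
    schur = pi * qtt - (qtt * b1 * b1 - 2 * q1t * b1 * b2 + q11 * b2 * b2) / det
    if schur <= 0:
        raise np.linalg.LinAlgError("slope information is not positive")
    return 1.0 / schur


def composite_gamma_variance_unit(
    w: WeightVector | np.ndarray, params: PopulationParams, design: TrialDesign
) -> CompositeVariance:
    """Variance of the composite-score treatment-effect estimator.

    Runs the J = 1 information machinery on the induced composite LMM with
    variance components (sigma_d2, sigma_a2); Var(gamma_hat_w) =
    sigma_gamma1_sq / N.  By the information inequality
    ``sigma_gamma1_sq >= w' Sigma_gamma1 w`` — collapsing to the composite
    score before fitting can only lose information.
    """
    if design.n_visits < 2:
        raise ValueError("at least two visits are required to identify the slope")
    wv = w.w if isinstance(w, WeightVector) else np.atleast_1d(np.asarray(w, dtype=float))
    sa2, sd2 = composite_variance_components(wv, params)
    if sd2 <= 0:
        raise ValueError("composite error variance w'Sigma_eps w must be positive")
    sg1sq = _univariate_gamma_variance(
        sd2, sa2, design.visit_times, design.allocation
    )
    return CompositeVariance(sa2, sd2, sg1sq)
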