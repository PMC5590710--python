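"""Trial simulation, known-covariance GLS fitting, Wald statistics, and
Monte-Carlo power — the brute-force check on the analytic engine.

Data are simulated exactly from the MLMM: each subject's random-intercept
vector is drawn MVN(0, Sigma_b) and each visit's error vector MVN(0,
Sigma_eps).  Arms are assigned deterministically (the first
ceil(N*allocation) subjects treated) so that empirical power targets the
design without randomization noise.  The fitter is the generalized
least-squares estimator of the fixed effects with the covariance matrices
treated as known — the estimator whose exact covariance the analytic engine
computes — so Monte-Carlo rejection rates estimate the same power the
noncentral chi-square formulas predict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    EffectSpec,
    PopulationParams,
    TrialDesign,
    WeightVector,
    composite_population,
    marginal_covariance,
)
from .power import PowerRequest

__all__ = [
    "LongitudinalDataset",
    "GLSFit",
    "WaldStatistics",
    "simulate_trial",
    "gls_fit",
    "wald_statistics",
    "evaluate_trial",
    "empirical_power",
]


@dataclass
class LongitudinalDataset:
    """Long-format longitudinal trial records on a common visit grid.

    ``values`` has shape (N, T, J); a subject's skipped visit is a row of
    NaN (the estimation module drops such rows; the GLS fitter requires
    complete data).  ``arm`` is 0/1 per subject, ``times`` the visit grid in
    years.
    """

    values: np.ndarray
    arm: np.ndarray
    times: np.ndarray
    labels: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.arm = np.asarray(self.arm, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        n, t, j = self.values.shape
        if self.arm.shape != (n,) or self.times.shape != (t,):
            raise ValueError("inconsistent dataset dimensions")
        if len(self.labels) != j:
            raise ValueError("labels must have one entry per component")
        self.labels = tuple(self.labels)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]

    @property
    def n_components(self) -> int:
        return self.values.shape[2]

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def composite(self, w: WeightVector | np.ndarray) -> "LongitudinalDataset":
        """Collapse components to the composite score w'Y (J = 1)."""
        wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
        return LongitudinalDataset(
            values=self.values @ wv[:, None],
            arm=self.arm,
            times=self.times,
            labels=("composite",),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (subject, visit), skipped visits omitted."""
        n, t, j = self.values.shape
        subject = np.repeat(np.arange(n), t)
        arm = np.repeat(self.arm, t)
        time = np.tile(self.times, n)
        flat = self.values.reshape(n * t, j)
        df = pd.DataFrame({"subject": subject, "arm": arm, "time": time})
        for k, lab in enumerate(self.labels):
            df[lab] = flat[:, k]
        keep = np.isfinite(flat).all(axis=1)
        return df.loc[keep].reset_index(drop=True)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, labels: Optional[tuple] = None
    ) -> "LongitudinalDataset":
        required = {"subject", "arm", "time"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"data is missing required columns {sorted(missing)}")
        if labels is None:
            labels = tuple(c for c in df.columns if c not in required)
        if not labels:
            raise ValueError("no component columns found")
        subjects = pd.unique(df["subject"])
        times = np.array(sorted(pd.unique(df["time"].astype(float))))
        t_index = {tv: i for i, tv in enumerate(times)}
        n, t, j = len(subjects), len(times), len(labels)
        values = np.full((n, t, j), np.nan)
        arm = np.zeros(n, dtype=int)
        s_index = {s: i for i, s in enumerate(subjects)}
        comp = df[list(labels)].to_numpy(dtype=float)
        for row, (s, a, tv) in enumerate(
            zip(df["subject"], df["arm"].astype(int), df["time"].astype(float))
        ):
            i = s_index[s]
            arm[i] = a
            values[i, t_index[tv], :] = comp[row]
        return cls(values=values, arm=arm, times=times, labels=tuple(labels))

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {k: v for k, v in self.meta.items()}
            meta.update(
                n_subjects=int(self.n_subjects),
                times=[float(t) for t in self.times],
                labels=list(self.labels),
            )
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=1)
            )

    @classmethod
    def read_csv(cls, path) -> "LongitudinalDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class GLSFit:
    """Known-covariance GLS fit of the MLMM fixed effects."""

    beta0_hat: np.ndarray
    beta2_hat: np.ndarray
    gamma_hat: np.ndarray
    gamma_cov: np.ndarray  # covariance of gamma_hat at the fitted N
    loglik: float


class WaldStatistics(NamedTuple):
    xi_j: float
    xi_jc: float
    xi_c: float


def simulate_trial(
    params: PopulationParams,
    design: TrialDesign,
    n_subjects: int,
    effect: Optional[EffectSpec] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> LongitudinalDataset:
    """Draw one complete trial from the MLMM.

    ``effect=None`` simulates the null (gamma = 0).  The first
    ceil(N * allocation) subjects are treated.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    gamma = (
        np.zeros(params.n_components)
        if effect is None
        else effect.gamma_for(params)
    )
    arm = np.zeros(n_subjects, dtype=int)
    arm[: math.ceil(n_subjects * design.allocation)] = 1
    values = _draw_values(params, design, arm, gamma, rng)
    return LongitudinalDataset(
        values=values,
        arm=arm,
        times=design.visit_times,
        labels=params.labels,
        meta={"seed": seed, "gamma": [float(g) for g in gamma]},
    )


def _draw_values(
    params: PopulationParams,
    design: TrialDesign,
    arm: np.ndarray,
    gamma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = arm.size
    times = design.visit_times
    t, j = times.size, params.n_components
    slope = params.beta2[None, :] + np.outer(arm, gamma)  # (N, J)
    mean = params.beta0[None, None, :] + times[None, :, None] * slope[:, None, :]
    chol_b = np.linalg.cholesky(params.sigma_b + 1e-300 * np.eye(j))
    chol_e = np.linalg.cholesky(params.sigma_eps)
    b = rng.standard_normal((n, j)) @ chol_b.T
    eps = rng.standard_normal((n, t, j)) @ chol_e.T
    return mean + b[:, None, :] + eps


def _design_for_times(times: np.ndarray, n_components: int, arm: int) -> np.ndarray:
    eye = np.eye(n_components)
    return np.vstack(
        [np.hstack([eye, t * eye, (t * arm) * eye]) for t in times]
    )


def gls_fit(dataset: LongitudinalDataset, params: PopulationParams) -> GLSFit:
    """Exact GLS fixed-effect estimates with known Sigma_b, Sigma_eps.

    Complete data on the visit grid is required; per-subject contributions
    reduce to per-arm sums because the design repeats within arm.
    """
    if not dataset.is_complete:
        raise ValueError("GLS fitting requires complete data on the visit grid")
    j = dataset.n_components
    if j != params.n_components:
        raise ValueError("dataset and params disagree on the number of components")
    v = marginal_covariance(params, dataset.n_visits)
    vinv = np.linalg.inv(v)
    xc = _design_for_times(dataset.times, j, arm=0)
    xt = _design_for_times(dataset.times, j, arm=1)
    flat = dataset.values.reshape(dataset.n_subjects, -1)  # (N, T*J) visit-major
    treated = dataset.arm == 1
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if (n_t == 0 or n_c == 0) and dataset.n_visits < 2:
        raise ValueError("design is singular: one arm and fewer than two visits")
    info = n_t * xt.T @ vinv @ xt + n_c * xc.T @ vinv @ xc
    rhs = xt.T @ vinv @ flat[treated].sum(axis=0) + xc.T @ vinv @ flat[
        ~treated
    ].sum(axis=0)
    try:
        theta = np.linalg.solve(info, rhs)
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("GLS design is singular") from exc
    resid_t = flat[treated] - xt @ theta
    resid_c = flat[~treated] - xc @ theta
    sign, logdet = np.linalg.slogdet(v)
    quad = np.einsum("ni,ij,nj->", resid_t, vinv, resid_t) + np.einsum(
        "ni,ij,nj->", resid_c, vinv, resid_c
    )
    n_obs = dataset.n_subjects * v.shape[0]
    loglik = -0.5 * (
        n_obs * np.log(2 * np.pi) + dataset.n_subjects * logdet + quad
    )
    return GLSFit(
        beta0_hat=theta[:j],
        beta2_hat=theta[j : 2 * j],
        gamma_hat=theta[2 * j :],
        gamma_cov=cov[2 * j :, 2 * j :],
        loglik=float(loglik),
    )


def wald_statistics(
    fit: GLSFit,
    weights: WeightVector,
    composite_fit: Optional[GLSFit] = None,
) -> WaldStatistics:
    """The three Wald statistics from fitted models.

    ``Xi_J`` and ``Xi_JC(w)`` come from the multivariate fit; ``Xi_C(w)``
    needs the GLS fit of the composite-score LMM (``composite_fit``).  For
    J = 1 all three coincide and ``composite_fit`` may be omitted.
    """
    g = fit.gamma_hat
    xi_j = float(g @ np.linalg.solve(fit.gamma_cov, g))
    w = weights.w
    xi_jc = float(w @ g) ** 2 / float(w @ fit.gamma_cov @ w)
    if composite_fit is None:
        if g.size != 1:
            raise ValueError("Xi_C requires the composite-score fit for J > 1")
        composite_fit = fit
    xi_c = float(composite_fit.gamma_hat[0]) ** 2 / float(
        composite_fit.gamma_cov[0, 0]
    )
    return WaldStatistics(xi_j=xi_j, xi_jc=xi_jc, xi_c=xi_c)


def evaluate_trial(
    dataset: LongitudinalDataset,
    params: PopulationParams,
    weights: WeightVector,
) -> WaldStatistics:
    """Fit both the multivariate and composite models and return all statistics."""
    fit = gls_fit(dataset, params)
    cfit = gls_fit(dataset.composite(weights), composite_population(weights, params))
    return wald_statistics(fit, weights, cfit)


def empirical_power(
    params: PopulationParams,
    design: TrialDesign,
    n_subjects: int,
    effect: Optional[EffectSpec],
    request: PowerRequest,
    reps: int = 2000,
    seed: int = 0,
) -> tuple:
    """Monte-Carlo rejection proportion of the requested test, with its SE.

    Each replicate simulates a full trial, fits it by known-covariance GLS,
    and compares the requested statistic with the central chi-square critical
    value at the request's df.  Returns ``(proportion, binomial SE)``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful estimate")
    rng = np.random.default_rng(seed)
    df = params.n_components if request.statistic == "J" else 1
    crit = stats.chi2.ppf(1.0 - request.alpha, df)
    weights = request.weights if request.weights is not None else WeightVector(
        np.ones(params.n_components)
    )
    rejections = 0
    for _ in range(reps):
        data = simulate_trial(params, design, n_subjects, effect, rng=rng)
        stats_all = evaluate_trial(data, params, weights)
        value = getattr(stats_all, f"xi_{request.statistic.lower()}")
        if value > crit:
            rejections += 1
    prop = rejections / reps
    se = math.sqrt(max(prop * (1 - prop), 1.0 / reps) / reps)
    return prop, se
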