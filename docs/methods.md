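# Methods

## Model

`mlmm-power` powers two-arm longitudinal trials whose endpoints are several
correlated component scores — the motivating case is early Alzheimer's
disease, with transformed MMSE, CDR-SB and ADAS-11 as the J = 3 components.
The j-th component score of participant n at visit time t (years) follows a
multivariate linear mixed-effects model (MLMM) with a shared random
intercept vector:

    Y_ntj = β_j0 + (β_j2 + γ_j · arm_n) · t + b_nj + ε_ntj,

with `b_n ~ MVN(0, Σ_b)` (between-subject correlation of levels),
`ε_nt ~ MVN(0, Σ_ε)` (within-visit correlation of scores), errors
independent across visits, and `arm_n ∈ {0, 1}`.  The treatment effect γ_j
acts on the annual rate of change β_j2.  There is no treatment main effect:
randomized arms share the baseline mean, which is what makes the precision
of γ̂ — and hence the optimal composite weights — depend on trial duration.

A composite score `C_nt = w'Y_nt` follows the induced univariate LMM with
variance components `σ_a² = w'Σ_b w` and `σ_δ² = w'Σ_ε w`; all machinery is
reused at J = 1 for it.

## Tests and power

Three Wald statistics, all built on the generalized-least-squares (GLS)
estimator of the fixed effects with Σ_b, Σ_ε treated as known:

| statistic | tests | null distribution |
|---|---|---|
| Ξ_J = γ̂'Σ_γ⁻¹γ̂ | any component effect | χ²_J |
| Ξ_JC(w) = (w'γ̂)²/(w'Σ_γ w) | the weighted effect w'γ | χ²_1 |
| Ξ_C(w) = γ̂_w²/σ_γ² | the effect in the composite-score LMM | χ²_1 |

Under an alternative γ* each is noncentral χ² with noncentrality N·λ₁,
where λ₁ is the per-participant noncentrality (`γ*'Σ_γ1⁻¹γ*`,
`(w'γ*)²/(w'Σ_γ1 w)`, `(w'γ*)²/σ_γ1²` respectively) and Σ_γ1 is the
γ-block of the inverse per-participant Fisher information averaged over
arms.  The required total size is `N = ⌈λ_req/λ₁⌉` with λ_req solved by
Brent bracketing of the noncentral-χ² power curve (tolerance 1e-10); the
continuous solution is rounded up, not to an even total.  One-sided Z
versions of the df-1 statistics use `λ_req = (z_{1-α} + z_power)²`.

Two orderings hold structurally and are property-tested:

* **information inequality** `w'Σ_γ1 w ≤ σ_γ1²(w)`: collapsing to the
  composite score before fitting can only lose information, so Ξ_JC(w) is
  at least as powerful as Ξ_C(w) for every w;
* **optimal weighting** `w_JC* ∝ Σ_γ1⁻¹γ*` attains the full joint
  noncentrality on one degree of freedom, so Ξ_JC(w_JC*) dominates Ξ_J.

`w_C*` maximizes `(w'γ*)²/σ_γ1²(w)`, which is not a Rayleigh quotient; it
is found by quasi-Newton search with the unit-norm constraint folded into
the objective (multi-start: equal weights, w_JC*, the unit vectors, and 32
random directions under a fixed seed; a candidate is accepted only with
projected-gradient norm below 1e-8 relative to the objective).  Weights are
L2-normalized and signed against the positive rate-reduction magnitudes, so
all reported entries are positive.

The Bonferroni comparator powers each component separately with Ξ_C at its
unit weight and level α/J and takes the largest N.

## Default parameters and design conventions

The packaged configuration (`data/adni_mci.yaml`) carries rates
β₂ = (0.079, 0.061, 0.055) per year and the two 3×3 covariance matrices
estimated on ADNI MCI participants (scores Box-Cox-transformed, scaled by
baseline SD, oriented so higher = worse).  Defaults: 25% reduction of every
rate (γ*_j = −0.25·β_j2), equal allocation, α = 0.05 two-sided, 80% power.

A d-year design with visit spacing Δ (default 0.5 y) schedules
**T = d/Δ visits at 0, Δ, …, d − Δ**; the 2-year biannual trial thus has
four scheduled visits.  This convention was fixed because it is the one
under which the published sample-size table is reproduced from the printed
parameter estimates (every cell within 2%, most within 1%); the alternative
grid running through d changes required sizes by up to a factor ~2 at short
durations.  Observation stacking is visit-major and the fixed-effect order
is (all β_j0, all β_j2, all γ_j) throughout.

Because the packaged inputs are the *printed* estimates (covariances
rounded to 2 decimals, rates to 3), recomputed optimal weights differ from
the published weight table by up to ~0.011 per entry; perturbing the inputs
within their printing precision reproduces the published weights almost
exactly, so the gap is input rounding, not model structure.  Sample sizes
are less sensitive (≤ ~2%).

## Simulation and Monte-Carlo power

The simulator draws complete data exactly from the MLMM; arms are assigned
deterministically (first ⌈N·allocation⌉ subjects treated) so rejection
rates target the design without randomization noise.  Each replicate is
fitted by the known-covariance GLS estimator — the estimator the analytic
engine describes — and the statistic is compared with the central χ²
critical value.  What passing Monte-Carlo checks shows is therefore that
the noncentral-χ² algebra is right *under the model's own assumptions*;
the generator shares those assumptions (Gaussian errors, no dropout, no
visit jitter, no autocorrelation, no floor effects), so agreement says
nothing about robustness to their violation on real cognitive scores.

## EM estimation

`em_fit` obtains maximum-likelihood estimates of (β, Σ_b, Σ_ε) by EM with
the random intercepts as missing data.  The E-step posterior of b_n is
conjugate-normal; the M-step is closed form (per-component least squares
for β — the error weighting cancels because every observed visit carries a
full component vector — and posterior-moment updates for both covariance
matrices).  Subjects may skip visits; subjects are grouped by observed
visit pattern and processed with dense vectorized algebra, so the cost per
sweep is essentially independent of N for balanced data.  Initialization is
per-component OLS with the pooled residual covariance split evenly between
Σ_b and Σ_ε; convergence is declared on relative log-likelihood change
(default 1e-8), and the trace is asserted non-decreasing to 1e-9 slack.
Partially observed component vectors within a visit are not supported, and
no Box-Cox pre-transformation is applied — inputs are assumed already
transformed and scaled.  Asymptotic fixed-effect SEs come from the
known-covariance Fisher information at the fitted covariances.

## Numerical choices

* Matrix work uses dense factorizations — the largest matrices are
  (J·T)² ≤ 39² — except the composite (J = 1) information, which uses the
  rank-one closed form of V⁻¹ for speed inside the w_C* optimizer (equal to
  the generic path to machine precision).
* Degenerate inputs: Σ_ε must be positive definite; Σ_b may be singular
  (a 1e-300 jitter guards the Cholesky in simulation only); weights
  orthogonal to γ* yield λ₁ = 0 with a warning and an explicit
  "undetectable" error at sample-size time; non-PD EM covariance updates
  are ridge-repaired at 1e-10 with a warning.
* Problem sizes used by the test suite and the reproduction script were
  chosen to keep each Monte-Carlo comparison at ≥ 3-binomial-SE
  resolution: 2000 replicates for the headline 6-year power check
  (N = 652), 400–800 for the power-grid checks, 50 repeated fits (N = 500)
  for EM bias, and N = 4000 subjects for the estimation-to-power closure
  check (which reproduces the analytic N within 5%).

## Known limitations

Random slopes, autocorrelated errors, dropout, unequal-allocation
optimization, covariate adjustment, group-sequential designs, and
zero-heavy/floor-effect component models are out of scope.  The one-sided
option covers only the df-1 statistics (the joint test's constrained
alternative leads to a chi-bar-square mixture that is not implemented).
Power results treat the covariance matrices as known; plugging in estimates
understates the true uncertainty, so sample sizes computed from pilot
estimates should be stress-tested by sensitivity analysis.
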