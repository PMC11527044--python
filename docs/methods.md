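# Methods

## The estimator class

`halcausal` implements the Highly Adaptive LASSO (HAL): empirical risk
minimization over the class of càdlàg (right-continuous with left limits)
functions whose *sectional variation norm* is bounded. For a function
f on [0, τ]^d the sectional variation norm

    ||f||_v = |f(0)| + Σ_{s ⊆ {1..d}, s ≠ ∅} TV(f_s)

sums the total variation of every coordinate section of f. Any such
function is a limit of linear combinations of tensor-product indicators
1{x_s ≥ u_s}, and — crucially — the sectional variation norm of the
combination equals the L1 norm of its coefficients. Risk minimization
under a variation-norm bound therefore reduces to a lasso:

    min_β  (1/n) Σ_i loss(y_i, β_0 + Φ(x_i) β)  +  λ ||β||_1

over the HAL design Φ of indicator (order 0) or hinge (order 1) bases
with knots at observed data points. We implement the Lagrangian form and
report the achieved ||β||_1 (plus |β_0|, which houses f(0); a switch
excludes it) as the variation-norm bound, exploiting the path
equivalence of the constrained and penalized problems.

Assumptions inherited by everything downstream: the true regression
functions are càdlàg with finite sectional variation norm. This is a
global complexity bound, not a local smoothness condition — jumps are
allowed — and it places the fits inside a Donsker class, which is what
licenses the first-order asymptotics used for inference.

## Basis construction (`basis`)

For each nonempty coordinate subset s with |s| ≤ `max_degree`, knots are
tabulated at the observed values (policy `all`, up to n·(2^d − 1)
candidate columns), at m per-coordinate empirical quantiles crossed into
tensor products (`quantiles(m)`), or at m k-means centroids per subset
(`kmeans(m)`, fixed clustering seed for deterministic builds). The
default `auto` policy uses `all` while the candidate count stays within
a 100 000-column budget and otherwise backs off to quantiles with the
largest m that fits. Duplicate columns on the training data are collapsed
to the lexicographically smallest (s, u) representative, recorded in
`dedup_map`. Indicators are closed at the knot (1{x ≥ u} = 1 at x = u),
giving càdlàg step-function fits; coordinates outside s are simply
omitted from the product. Designs are built and stored sparse (CSC).

Spline orders 0 and 1 are supported; higher orders are out of scope.

## Solving the lasso (`_solver`, `fit`)

Two interchangeable engines, cross-checked in the tests:

* **Exact homotopy (LARS).** Gaussian fits with strictly positive penalty
  factors are solved by the LARS-lasso path (scikit-learn), which is
  piecewise linear in λ, so solutions at the requested 100-point grid are
  exact interpolations. The intercept is left unpenalized by centering
  the columns (slope coefficients are unchanged, so the variation-norm
  identity is preserved); non-uniform penalty factors are absorbed by
  column scaling.
* **Coordinate descent (numba).** The binomial family (IRLS with penalized
  weighted-least-squares inner solves), zero penalty factors, and the
  bootstrap refits use cyclic coordinate descent on the CSC arrays with
  an active-set schedule. Convergence is declared when the largest
  single-coordinate objective decrease falls below tol × the weighted
  outcome variance (tol = 1e-7), the standard objective-scaled criterion
  for this solver family. We chose it over a raw coefficient-change
  threshold after observing that near-duplicate indicator columns make
  the latter iterate ~100× longer for no measurable statistical gain;
  solution objectives agree with the exact LARS route to ~1e-7 relative.

Columns are never standardized — standardization would break the
"L1 norm = variation norm" identity — and the intercept is never
penalized. Per-column penalty factors (0 allowed) let prior-knowledge
bases enter unpenalized.

The λ grid is 100 log-spaced values from λ_max (smallest penalty with all
coefficients zero) down to 1e-4·λ_max, and V-fold cross-validation
(default V = 10, seeded fold assignment) selects λ with ties resolved to
the larger penalty. Within each training fold, columns that coincide on
the fold's rows are collapsed before solving, mirroring dictionary
dedup — without this the homotopy solver is handed exactly collinear
columns and its interpolated coefficients can explode.

**Relaxed HAL** refits the selected support without a penalty (least
squares, or Newton/IRLS for binomial), dropping exactly collinear support
columns first-come-first-kept. **Undersmoothing** scans the path from
λ_cv toward weaker penalties and returns the first penalty at which the
empirical mean of a target score is within σ_n/(√n · log n) of zero,
σ_n² being the empirical score variance; if no grid point qualifies, the
weakest penalty is returned with a flag.

## ATE estimation (`causal`)

The target is ψ = E[Q̄(W,1) − Q̄(W,0)]. The outcome regression Q̄ is fit
as a single HAL regression on the joint (W, A) design, so
treatment-covariate interactions enter through tensor products; the
propensity g is a binomial HAL on W, with predictions truncated to
[0.005, 0.995] by default (all truncations counted in diagnostics).

* **Plug-in** averages Q̂(W,1) − Q̂(W,0) with no correction; its reported
  standard error uses the efficient influence curve

      D*(O) = Q̄(W,1) − Q̄(W,0) − ψ + (A/g(1|W) − (1−A)/g(0|W))(Y − Q̄(W,A)).

* **IPTW** uses Horvitz–Thompson weighting; with `undersmooth=True` the
  propensity penalty is re-selected along its path with the EIC mean as
  the score, which is what makes the weighted estimator solve the
  efficient score equation.
* **TMLE** runs a one-dimensional logistic fluctuation
  logit Q̄* = logit Q̄ + ε·H with clever covariate
  H = A/g(1|W) − (1−A)/g(0|W), the covariate-in-regression form whose
  ε-score is exactly the residual part of Pn D*. Continuous outcomes are
  affinely mapped to [0,1] using the observed range (inverted on output),
  which keeps the update inside the bounded-outcome model and hence keeps
  ψ̂ inside its global bounds for binary outcomes. ε̂ is found by bracketed
  Brent root-finding on the score — the score is strictly monotone in ε —
  so |Pn D*| after targeting is at solver precision (~1e-14 in practice;
  tests assert 1e-8).

`exact_remainder_ate` evaluates the second-order remainder
R2(P, P0) = Ψ(P) − Ψ(P0) + P0 D*(P), which for the ATE is the
product-form expectation of propensity error times outcome-regression
error (per treatment arm) over the covariate distribution. It vanishes
when either nuisance is correct — double robustness — and the tests
verify both zeros at machine precision plus a constant-error closed form.

## Inference (`inference`)

**Wald**: ψ̂ ± z · sd(D*)/√n, normal quantiles, no t correction.

**Nonparametric bootstrap with plateau selection.** First-order Wald
intervals undercover when the remainder is not negligible, so for each
penalty λ in a grid restricted to fits whose L1 norm is at least the
CV-selected norm (λ ≤ λ_cv), each of B row resamples refits the outcome
lasso at λ (support re-selected within the resample), relaxes it, and
reruns the targeting step; the interval at λ is
ψ̂_original(λ) ± z·sd(bootstrap ψ*) (percentile variant available).
Widths grow as the penalty weakens and stabilize once the fit captures
the true function; the final interval is taken at the plateau onset.
The plateau selector computes discrete second differences of the width
curve with respect to grid index (optional window-3 moving average,
off by default so the selector is transparent) and picks the point of
extremal concave curvature, ties to the larger penalty; linear or
constant width curves return the largest penalty with a warning. The
selector is invariant to rescaling the widths.

Default bootstrap grid: `grid_size = 10` penalties among the 40 path
points past λ_cv. Per resample the propensity's relaxed coefficients are
refit by Newton on the support selected by the original CV fit; a flag
(`reselect_g_support`) re-runs the full propensity lasso per resample
instead. We default to the frozen-support refit because the procedure's
penalty grid concerns the targeted nuisance, and pilot runs showed the
full re-selection changes interval widths by less than Monte-Carlo noise
at ~20× the cost. Resamples containing a single treatment arm are
rejected and redrawn (capped at 10·B).

**Working-model (delta-method) inference.** Treating the relaxed fit's
support as a fixed parametric model, `working_model_covariance` returns
the HC0 sandwich covariance of (intercept, support coefficients).
`cate_curve` evaluates τ̂(w) = Q̂(w,1) − Q̂(w,0) = c(w)ᵀβ̂ with pointwise
variance c(w)ᵀ Σ̂ c(w); `dose_response_curve` evaluates
θ̂(a) = (1/n) Σ_i Q̂(W_i, a) with the basis evaluations averaged over the
empirical covariate distribution. Simultaneous bands use the max-|Z|
quantile over the evaluation grid from 10⁴ seeded draws of a centered
Gaussian with the estimates' correlation structure, floored at the
pointwise quantile so bands never undercut pointwise intervals.
*Caveat*: the covariance conditions on the data-selected support; its
validity as an approximation rests on the working model being learned
consistently, and coverage statements are asymptotic in that sense.

## Synthetic data (`dgp`)

The generators define the study conditions for every test:

* **Sinusoid** (univariate regression): X ~ U(−4,4),
  Y = 2 sin((π/2)|X|) + N(0,1), n = 500 in the reference experiment. The
  mean function traverses eight monotone arcs of height 2, so its true
  sectional variation norm is 16 (|f(−4)| = 0); `true_variation_norm_1d`
  is the independent grid oracle for this quantity (error O(1/grid)).
* **linear**: W ~ U(0,1)², g0(1|W) = expit(2(W1 − ½)),
  Q̄0 = W1 + 0.5·A (+ optional A×W interactions), noise sd 1;
  ψ0 = 0.5 + ½·Σγ in closed form.
* **null**: A ~ Bernoulli(½) independent of (W, Y); ψ0 = 0.
* **near-positivity**: g0(1|W) = expit(−7 + 8·W1), dipping to ~1e-3 near
  W1 = 0 so a region of covariate space has treatment probabilities in
  [0.001, 0.02] — the practical positivity violation regime.
* **logistic**: binary Y with Q̄0 = expit(−0.5 + W1 + 0.8·A); ψ0 is
  closed-form since expit integrates analytically against U(0,1).
* **dose** (`gen_dose_dgp`): continuous A ~ U(0,1) with a linear dose
  effect (zero in the null variant), for dose-response band checks.

Each generator draws from a single seeded `numpy` Generator per call:
identical arguments give byte-identical data. Truths are verified
against large-sample Monte-Carlo oracles in the tests. What these DGPs
do **not** emulate: heavy-tailed noise, discrete or high-dimensional
covariates, treatment-dependent variance, measurement error, or
censoring — passing tests demonstrate correctness of the estimators
under the stated models, not robustness to those features.

## Problem sizes used in the test suite

Simulation tests are sized to run on a single CPU: the coverage study
uses 200 replications at n = 500 with quantile knots (m = 5), 5-fold CV,
a 30-value outcome-penalty grid, a 20-value propensity grid, B = 200
bootstrap resamples over a 4-penalty grid; the TMLE score-equation sweep
uses 100 datasets at n = 200; the asymptotic-linearity check uses 40
replications at n = 400 with a widened tolerance band reflecting the
replication count. The sinusoid experiment runs at its reference size
(n = 500, all knots, 10-fold CV, 100 penalties).

## Known limitations

* Spline orders k ≥ 2, monotonicity constraints, conditional-density
  losses, super-learner ensembling, cross-fitting/CV-TMLE, and the
  adaptive-TMLE/working-model-projection machinery are out of scope.
* The binomial coordinate-descent path is markedly slower than the
  gaussian homotopy at very weak penalties (IRLS near saturation);
  propensity grids default to the same 1e-4 ratio but simulations pass
  1e-2 where the deep tail is not needed.
* Post-selection inference for the working-model bands is approximate,
  as discussed above.
* `enumerate_knots` with policy `all` scales as n·(2^d − 1) columns; the
  automatic quantile fallback caps memory but coarsens the sieve.
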