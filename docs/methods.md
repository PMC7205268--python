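# Methods

## Estimators

**Component-wise median** — the vector of marginal sample medians
(even-sample convention: mean of the two central order statistics).
Translation-equivariant but not orthogonally equivariant.

**Spatial (L1) median** — the minimiser of `Σᵢ ‖xᵢ − m‖`, computed by the
Weiszfeld fixed-point iteration started at the component-wise median, with
the Vardi–Zhang correction when an iterate coincides with a data point
(the reweighted step is mixed with the current iterate in proportion
η/‖R‖, where η is the coinciding multiplicity and R the residual
gradient; if ‖R‖ ≤ η the iterate already satisfies the subgradient
optimality condition).  Defaults: relative step tolerance `1e-8`, at most
500 iterations; non-convergence is flagged in the diagnostics rather than
raised, because a near-optimal iterate is still a usable location.

**Projection median** — `n ∫ med(X_a) df(a)` over the unit sphere.  Two
quadratures:

* *Monte Carlo*: `(n/J) Σⱼ med(X_{aⱼ})` over J directions obtained by
  normalising i.i.d. standard-Gaussian vectors (exactly uniform on the
  sphere, trivially seedable).  Default J = 20000; the error decays as
  J^{-1/2}.
* *Trapezoidal*: in 2-D one composite trapezoidal rule over θ ∈ [0, 2π]
  applied componentwise to `med(X_θ)` and divided by π; in 3-D a nested
  rule over (θ₁, θ₂) ∈ [0, π] × [0, 2π] with the volume-element weight
  sin θ₁, normalised by the identically gridded quadrature of the bare
  weight (→ 4π) and multiplied by n = 3.  Both endpoint nodes are kept;
  the duplicated periodic node gets the standard half weight.  The 2-D
  rule is spectrally accurate (trigonometric integrand over a full
  period); the 3-D θ₁ integral is not periodic and converges at O(h²).
  Default 36 subintervals per integral, the smallest count that is
  accurate without excessive work; below 15 a warning is issued.  Higher
  dimensions are not gridded — the cost grows geometrically, which is
  exactly the regime Monte Carlo and yamm cover.

Both routines internally centre the cloud at its marginal median and add
it back afterwards.  Analytically this changes nothing (the definition is
translation-equivariant); numerically it makes translation equivariance
exact for a fixed seed or grid and removes the bulk-location component of
the integration error — without it, the finite-J direction average
`(n/J) AᵀA` differs from the identity by O(J^{-1/2}) and even a
single-point cloud would be recovered only approximately.

**yamm** — minimise `M_{X,m}(μ) = ∫ m_X(μ, a)² da` over μ, where
`m_X(μ, a)` is the univariate median of the projections of the shifted
cloud.  The integral is estimated by `J⁻¹ Σⱼ m_X(μ, aⱼ)²` with a
direction set drawn **once** per call and reused for every objective
evaluation (common random numbers).  A per-evaluation resample would make
the objective stochastic and defeat quasi-Newton line searches; with a
fixed set the objective is deterministic, piecewise smooth, and BFGS with
numerical gradients handles the isolated non-smooth points in practice.
Defaults: J = 2000 directions, start at the spatial median, BFGS,
`reltol = 1e-6` (mapped to the optimiser's gradient/function tolerance as
appropriate: `gtol` for BFGS/CG, `ftol` for L-BFGS-B, `fatol` for
Nelder-Mead; the `sann` tag maps to scipy's dual-annealing with bounds
spanning the data).  The squared objective (`doabs = 0`) is the default;
the absolute variant gives similar minimisers on well-conditioned clouds.
The minimiser of the population objective is the projection median, so at
matched accuracy the two routes must agree — the test suite checks
`‖yamm − trapz‖` at the Monte Carlo noise scale.

## Influence theory on a contaminated mixture

The mixture `(1−ε)N(ν₁, Σ₁) + εN(ν₂, Σ₂)` in 2-D, with the first
component the bulk.  Projected onto direction θ after shifting by μ, the
component means are `sᵢ = (νᵢ₁−μ₁)cos θ − (νᵢ₂−μ₂)sin θ`; with identity
covariances (assumed for all closed forms; the CDF helper also handles
general covariances through the projected variances) the projected
mixture CDF is `F(y) = (1−ε)Φ(y−s₁) + εΦ(y−s₂)`.

* *Exact projected median*: the root of `F(y) = 1/2`, bracketed around s₁
  and solved by Brent's method.
* *Taylor approximation*: expanding F around s₁ and solving the
  linearised equation gives

      y_m ≈ s₁ + ε √(π/2) (2Φ(s₂−s₁) − 1) / (1 − ε + √(2π) ε φ(s₂−s₁)).

  The denominator is `√(2π) F′(s₁) > 0`, so the expression is finite for
  all arguments and reduces to s₁ when ε = 0 or s₁ = s₂.  The error is
  O(ε²); the suite verifies the empirical order against the root finder.
* *General closed form*: integrating the squared Taylor median over θ
  with the cosine approximation `φ(z) ≈ (1 + cos z)/2π` (valid on
  (−π, π); it integrates to 1 there) yields

      μ* = ν₁ + π^{-1/2} R ε (1 − R²/32 + R⁴/1536) (cos α, sin α),

  with R the inter-mean distance and α = atan2(δ₂, δ₁) the outlier
  direction.  Two validity thresholds on R circulate — R < 2π
  (worst-case per direction) and R < √2 π ≈ 4.44 (which matches where the
  approximation visibly breaks away) — and `approx_validity` reports both
  rather than adjudicating.  Because of the cosine approximation this
  form sits ≈ 20% below the axis-aligned form even at small R; the two
  agree in order of magnitude, not digit-for-digit.
* *Axis-aligned closed form*: for ν₁ = 0, ν₂ = (0, d) the θ-integral can
  be done exactly, giving
  `μ₂* = 2^{-1/2} ε d e^{-d²/8} (I₀(d²/8) + I₁(d²/8))`.  Evaluated with
  exponentially scaled Bessel functions; beyond z = d²/8 ≈ 10⁸, where the
  library implementation degrades, the uniform asymptotic expansion
  `e^{-z} Iₙ(z) ~ (2πz)^{-1/2}(1 − (4n²−1)/(8z))` is spliced in, so the
  curve attains its limit `2^{3/2} ε/√π` without overflow.

The *numerical* influence curve draws, for each outlier distance d,
`reps` samples from the axis-aligned mixture, computes yamm on each and
averages the second coordinate.  The per-realization sample size defaults
to 100 points — large enough that sampling noise does not mask the
plateau, small enough to keep the experiment at desk scale — and is a
parameter.  The reduced experiment in the test suite uses reps = 100 and
500 projections per yamm call on a d-grid of 0..10 by 0.4; assertions are
made on segment means with propagated Monte Carlo standard errors, not on
single noisy grid points.

## Muqie contours

A muqie point `Q(α, u)` is the unit direction u rescaled by the empirical
α-quantile (type-7, linear interpolation of order statistics) of the
data's projections onto u after centring at a robust location (yamm by
default; spatial, component-wise, mean, or an explicit centre are
accepted).  Quantiles keep their sign: at sub-median levels a direction's
point can land on the opposing side of the centre, which is precisely
what makes cluster structure visible in low-α frames.  Direction grids:
regular angles (default 360) in 2-D, a latitude–longitude grid (default
24 × 48) in 3-D.  Frames across an increasing α-ladder share one centre
and grid, so per-direction radii are non-decreasing and the contours grow
outward; each frame exports to CSV (and optionally PNG) for external
animation assembly.  These are *not* true multivariate quantiles — no
mass-interpretation of the enclosed region is claimed.

## Simulation benchmarks

**Data generator.** The canonical benchmark distribution is the
rotationally symmetric bivariate Laplace, sampled as `X = √(W) Z` with
`W ~ Exp(1)` and `Z ~ N(0, 2b² I)`; a variant with i.i.d. Laplace(0, b)
marginals is also provided.  The default scale is b = √5, i.e.
per-component variance 10, fixed by the analytic identity
`MSE(mean) = 2b²/k` against the benchmark's reference levels.  The choice
between the two Laplace readings matters: under i.i.d. marginals the
component-wise median is the most efficient of the medians, whereas under
the symmetric law the spatial and projection medians win — the latter is
the regime this benchmark is designed to exhibit, and only it reproduces
the reference orderings, so the symmetric law is the default.

**MSE criterion.** `MSE = n⁻¹ E‖est − μ‖²` with μ = 0 by construction;
each (estimator, k) cell averages `reps` replicates (default 1000) and
reports the Monte Carlo standard error.  All estimators see the same
clouds at a given k, so comparisons are paired.  The projection-median
entry uses the trapezoidal method with 36 subintervals.

**Breakdown probe.** A standard-normal bulk of k points with ⌊fk⌋ points
moved to distance 10⁶ along a random direction; the estimate is "bounded"
if it stays within 10× the bulk radius.  The scan over the contamination
count locates the empirical breakdown fraction; for the projection median
at k = 100 it is 0.5 — bounded at 49 contaminants, unbounded from 50
(at exactly half, the even-sample median convention already averages a
bulk and an outlier order statistic).

**What the synthetic data does not emulate.** The generators produce
i.i.d. rows from clean parametric families (plus point-mass outliers);
real morphometric or clustered data have correlated errors, unequal
cluster shapes and measurement artefacts.  Passing benchmarks therefore
certify the estimators' statistical behaviour under the stated models,
not performance guarantees on any particular real dataset.

## Numerical choices and limitations

* Seeds: every stochastic routine accepts an integer seed or numpy
  Generator; multi-stage experiments spawn child streams from a single
  `SeedSequence`, so adding a stage does not perturb earlier streams.
* The yamm objective is non-smooth where a projected median ties between
  data points; no special handling is applied (numerical-gradient BFGS
  tolerates it, and the Nelder-Mead fallback is available).
* Trapezoidal quadrature is limited to n ∈ {2, 3} by design; use the
  Monte Carlo route or yamm in higher dimensions.
* The closed-form influence results assume identity covariances and small
  ε; the general closed form additionally degrades for inter-mean
  distances beyond ≈ 4.4 and should not be used there.
* Benchmark absolute levels depend on the Laplace scale b; orderings
  (medians beat the mean on long-tailed data, spatial ≈ projection) are
  scale-free.
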