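# yamm — projection medians, influence curves and muqie contours

Robust multivariate location estimation for numeric point clouds.  The
centrepiece is the **projection median**: for a finite set **X** ⊂ ℝⁿ
(n ≥ 2) it integrates the median of the one-dimensional projections of
**X** over all directions on the unit sphere,

    M_P(X) = n ∫ med(X_a) df(a),    med(X_a) = a · median_i ⟨x_i, a⟩,

with *f* the normalised uniform measure on the sphere (in 2-D this reads
`π⁻¹ ∫₀^{2π} med(X_θ) dθ`).  The projection median has breakdown point 1/2
in every dimension — up to half the sample can be corrupted arbitrarily
without carrying the estimate away — which makes it attractive wherever a
"middle" of noisy multivariate measurements is needed: morphometrics,
epidemiological summaries, outlier-contaminated sensor data.

Three interchangeable computations are provided:

* **Monte Carlo integration** (`projection_median_mc`) — average
  `n · med(X_a)` over many random unit directions; any n ≥ 2.
* **Trapezoidal quadrature** (`projection_median_trapz`) — the integral in
  spherical coordinates, one angle grid in 2-D, a nested sin-weighted grid
  in 3-D; fast and accurate in low dimensions.
* **yamm** ("yet another multivariate median", `yamm`) — minimise the
  integrated squared projected median over the shift vector μ,

      M_{X,m}(μ) = ∫_{‖a‖=1} m_X(μ, a)² da,   m_X(μ, a) = median_i ⟨x_i − μ, a⟩,

  with a Monte-Carlo objective and a BFGS optimiser.  The minimiser is
  equivalent to the projection median, but a good starting point (the
  spatial median) lets yamm reach it with far fewer projections than
  direct Monte Carlo integration.

Around the estimators the package supplies: the classic component-wise and
spatial (Weiszfeld/Vardi–Zhang) medians; closed-form and numerical
influence curves of yamm on a contaminated bivariate normal mixture
`(1−ε)N(ν₁, I) + εN(ν₂, I)`, including the Bessel-function form of the
influence for an axis-aligned outlier component; **muqie**
(MUltivariate QuantIlE) contours — directions rescaled by projected
empirical quantiles around a robust centre — with frame export for
animated, growing-α displays; and MSE / breakdown simulation benchmarks
on bivariate Laplace data.

## Worked example

Three Gaussian clusters (120 points) plus two outliers planted at distance
~1400 from the data:

```python
import numpy as np, yamm

X = yamm.cluster_fixture(
    [((0.0, 0.0), 0.4, 40), ((9.0, 1.0), 0.4, 40), ((3.0, 6.0), 0.4, 40)],
    outliers=[(1000.0, 1000.0), (1000.0, -1000.0)], seed=7)

print(yamm.projection_median_trapz(X, 36).location)   # [3.559 2.775]
print(yamm.yamm(X, nprojs=2000, seed=1).location)     # [3.537 2.752]
print(yamm.spatial_median(X).location)                # [3.583 2.908]
print(yamm.sample_mean(X).location)                   # [20.272  2.234]
```

The three medians agree to ~0.1 and sit in the middle of the cluster
triangle; the mean is dragged 17 units toward the outliers.  Diagnostics
travel with each estimate — for the yamm call above,
`{'objective': 1.524, 'nfev': 12, 'njev': 4, 'converged': True}`: the
optimiser needed 12 objective evaluations and 4 gradients.

The closed-form influence approximation for an outlier component at
distance d, `2^{-1/2} ε d e^{-d²/8} (I₀(d²/8) + I₁(d²/8))`, gives 0.0567
at (ε = 0.05, d = 2) and saturates at `2^{3/2} ε/√π ≈ 0.0798` — the
plateau that certifies robustness:

```python
yamm.yamm_approx_axis(2.0, 0.05)   # array([0.    , 0.0567])
```

The same functionality is scriptable through the `pmed` CLI:

```sh
pmed --method trapz --subintervals 36 points.csv
pmed --method yamm --nprojs 2000 --seed 1 points.csv
pmed muqie --alpha 0.8 --directions 360 --out contour.csv points.csv
pmed influence --eps 0.05 --reps 100 --seed 1 --out curve.csv
pmed bench --reps 1000 --seed 1 --out report.csv
```

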