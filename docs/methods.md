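# Methods

## The model

satkin models saturation phenomena with the hyperbola

    y(x) = x / (1/κ₀ + x/Y_sat),   x ≥ 0,

the unique solution of the fractional-change differential equation
dκ/κ = N·(dy/y) − M·(dx/x), κ = dy/dx, for N = M = 2 under the physical
boundary conditions (finite initial slope at x → 0, finite asymptote at
x → ∞). Integrating the equation once gives the slope law
dy/dx = (1/C)·yᴺ/xᴹ; for N = M = 2 the constant C is κ₀ and a second
integration gives y = x/(C₁ + C₂x) with C₁ = 1/κ₀, C₂ = 1/Y_sat.

Assumptions: y is monotone increasing and concave in x, passes through
the origin, and approaches a finite asymptote; a single class of
independent, identical interactive sites (no cooperativity — Hill
exponents ≠ 1, multi-site heterogeneity and progress-curve kinetics are
out of scope). The parameterisation is deliberately (κ₀, Y_sat), the two
quantities read directly off a data plot; K = Y_sat/κ₀ is derived. A
conversion constructor `SaturationCurve.from_half_saturation` accepts
(K, Y_sat).

κ₀ is treated strictly as the slope dy/dx in the limit x → 0, in y-units
per x-unit. In the ligand-binding literature the same quantity is
sometimes read as a binding *rate* per unit time by fixing the
observation window; satkin carries units as opaque labels and leaves any
time reading to the caller.

## Numerical choices

* **Stability.** All probabilities use the cancellation-free forms
  Γ_fr = K/(K+x) and Γ_bd = x/(K+x); the curve is evaluated as
  Y_sat·x/(K+x). x < 0 is rejected (the model has no meaning there);
  x = 0 is valid everywhere, with the exact limits y = 0, Γ_fr = 1,
  slope = κ₀.
* **DE residual.** The identity is checked in derivative form
  r = y″/y′ − N·y′/y + M/x. The terms scale as 1/x, so an absolute
  residual tolerance is meaningful at moderate parameter scales; the
  model's scale invariance means nothing new is probed at extreme ones.
* **Integration.** The slope law is integrated with an 8th-order
  adaptive Runge–Kutta method (DOP853, rtol 1e-10). Integration cannot
  start at x = 0 (the M/x term is singular); verification grids start at
  the first grid point with y₀ from the closed form, and the generic
  start for unknown families is x₀ with y₀ from the data.
* **Slope-change ratio.** The finite-difference ratio
  [(1/2)·y″·dx]/[Δ(y/x)] converges to Γ_fr first order in dx; the ½
  factor in the slope change is required for that limit (without it the
  ratio converges to 2·Γ_fr), and the convergence test asserts exactly
  this.
* **Family discrimination.** For each integer pair (N, M) in the search
  grid the constant C is fitted by least squares on
  log κ = −log C + N·log y − M·log x, with slopes estimated by central
  differences in log–log space (dy/dx = (y/x)·d ln y/d ln x — exact for
  power laws and second-order accurate on geometric grids; the one-sided
  endpoint estimates are discarded, smoothing is off by default). The
  slope law is then integrated from the first data point and the pair is
  scored by the sum of squared relative deviations; ties break toward
  smaller N+M, then smaller N. Exponents are integers in [1, 6];
  fractional exponents are out of scope.
* **Estimation.** The linear transform fits x/y on x by ordinary least
  squares (the classical plot does not specify a weighting; OLS is
  adopted), and maps back exactly: κ₀ = 1/intercept, Y_sat = 1/slope.
  NLS minimises y-space residuals with parameters on the log scale so
  positivity is structural, initialised from the linear transform (with
  a two-point fallback), Levenberg–Marquardt, tolerances 1e-15. Weight
  schemes: uniform (default), 1/y, 1/y² — the last approximates
  relative-error loss and is the appropriate choice under proportional
  noise. x = 0 points are excluded from the transform (uninformative
  there) but retained in NLS, since the model passes through the origin
  exactly. Non-saturating data (non-positive transform slope/intercept,
  or optimizer failure) produce an explicit failure result, never
  silently negative constants.
* **Bootstrap.** Case resampling with a seeded generator; percentile
  95% intervals; if more than 20% of resamples fail to fit, intervals
  are reported unavailable with a diagnostic.

## The synthetic-data generator

`SimSpec`/`generate` emulate the classical saturation experiment:
strictly positive design points read off a true curve plus seeded noise.
Designs: `linear` (arithmetic grid up to x_max), `log` (constant-ratio
grid spanning [x_min_multiple·K, x_max_multiple·K]; the default spans
[K/5, 10K], covering Γ_fr from ≈0.83 down to ≈0.09 where both constants
are informative), and `geometric` (a doubling grid anchored at x_max).
Noise: additive Gaussian (constant σ) or proportional (constant CV);
draws landing at y ≤ 0 are redrawn up to 100 times rather than clipped,
a deliberate truncation that avoids a point mass at zero which would
bias fits. Default simulated conditions used throughout the tests:
n = 12 points, the default log span, proportional noise at CV = 2% where
noise is wanted.

What the generator does *not* emulate: errors in x (errors-in-variables),
systematic drift, heteroscedasticity beyond the two noise laws,
outliers, and time-course measurement. Tests passing on these fixtures
demonstrate correctness of the algebra and estimators under the stated
noise laws, not robustness to real-world artefacts beyond them.

## Design choices in open territory

* **Inhibition signatures.** The classification table maps the observed
  trends of (P_sat, κ₀) — each either unchanged or decreased within a
  relative tolerance — and of their ratio K_m onto the five classical
  inhibition cases; it is exposed as data
  (`satkin.domains.INHIBITION_SIGNATURES`) rather than hard-coded logic.
  The constraint that no basic constant may increase under an inhibitor
  makes any observed increase the verdict `inconsistent`. The default
  tolerance is rel_tol = 0.02, suited to near-noiseless fits; it is
  configurable per call and must exceed the sampling error of the fitted
  ratios to be meaningful. In the noisy classification tests (CV = 2%)
  a triplicate design is used — standard practice for inhibition assays —
  with rel_tol = 0.05, about five times the resulting ratio standard
  error.
* **Bootstrap coverage.** Percentile intervals at n ≈ 12 with a
  mis-specified loss (uniform weights under proportional noise)
  undercover mildly (high 80s% observed at nominal 95%); with weights
  matched to the noise law (1/y² under proportional noise) and n = 16
  design points, coverage is within sampling error of nominal. The
  coverage test uses the matched configuration; the mismatch behaviour
  is a known limitation of small-sample percentile bootstraps, not a
  defect of the estimator.
* **Replicates** are fitted as individual points by default;
  `average_replicates=True` reproduces classical pre-averaged plots.
* **Problem sizes.** Monte-Carlo assertions use 100–500 seeded
  replicates at n = 12–16 points — large enough that the asserted
  medians, RMSE orderings and coverage proportions are stable across
  reruns, small enough that the whole suite runs in about a minute.

## Known limitations

* Only the N = M = 2 family member has a closed form here; other (N, M)
  are handled numerically.
* The linear transform's estimates are noise-sensitive (its κ₀ RMSE at
  CV = 5% is roughly twice that of 1/y²-weighted NLS; the suite asserts
  this ordering). It is retained as the classical procedure and as the
  NLS initialiser.
* No errors-in-x model, no sigmoidal alternative comparison, no
  inhibitor dose-series (K_i) estimation.
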