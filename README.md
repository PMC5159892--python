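# growthgp

Non-parametric inference of time derivatives from noisy time series using
Gaussian processes, aimed at microbial growth curves: given plate-reader
optical densities (or any repeated measurement over time), `growthgp`
infers the latent curve, its first and second time derivatives, and
growth summary statistics — maximum specific growth rate, lag time,
doubling time — each with an error estimate.

## The method

Observations are modelled as y_i = f(x_i) + ε_i with f drawn from a
zero-mean Gaussian process, f ~ GP(0, k(x, x′; θ)), and ε_i independent
Gaussian noise of variance σ². Replicates are combined by simply pooling
all points. The kernel hyperparameters θ (amplitude, flexibility) and σ²
are found by maximizing the marginal likelihood

    log P(y | θ, X) = −½ yᵀ(K + σ²D)⁻¹y − ½ log det(K + σ²D) − (n/2) log 2π

with bounded L-BFGS-B runs from random starts in a log₁₀ box (D is the
identity, or an empirically estimated per-time relative noise profile
computed from replicate scatter). Because differentiation is linear, the
derivatives g = f′ and h = f″ are Gaussian processes too, with covariances
given by partial derivatives of the kernel (∂₁ᵏ∂₂ˡ k, implemented in closed
form for the squared-exponential, Matern ν=5/2 and neural-network kernels).
Conditioning the joint Gaussian of (y, f*, g*, h*) on the data yields the
posterior mean and full covariance of the curve and both derivatives at any
prediction times.

Fitting is done on the natural log of the measurements, so g is the
specific growth rate d ln y/dt. Summary statistics are computed per sample
of the joint posterior — max growth rate = max_t g(t), doubling time
= ln 2 / max rate, lag time = intercept of the tangent at the point of
maximum growth rate with the initial log-measurement — and reported as the
mean ± sd over (by default) 100 samples, which propagates the full
inference uncertainty, correlations included.

Kernels: the squared exponential (smooth latent functions; supports f, g
and h) is the default; Matern ν=5/2 assumes only twice-differentiable
latent functions (f and g only — its second derivative would be
meaninglessly rough); the neural-network (arcsine) kernel prefers
sigmoid-shaped functions and suits sparse single-replicate data.

## Worked example

Simulate a three-replicate growth curve from the built-in weighted
Gompertz + Richards mixture and fit it:

```sh
growthgp simulate --n-points 100 --n-replicates 3 --seed 11 --out growth.tsv
growthgp fit --input growth.tsv --seed 1 --out-dir fit_out
```

`fit_out/statistics.tsv` then contains

```
      statistic   mean       sd  n_samples  n_excluded
max_growth_rate 0.2134 0.005043        100           0
    time_of_max  6.861   0.1007        100           0
       lag_time  2.894  0.09272        100           0
  doubling_time  3.249  0.07688        100           0
```

i.e. a maximum specific growth rate of 0.213 ± 0.005 per unit time,
reached at t ≈ 6.9, a lag of about 2.9 time units and a doubling time of
3.25 ± 0.08 — each sd coming from 100 joint posterior samples (the exact
mixture's peak rate is ≈0.21, within the error bar of the estimate).
`fit_out/predictions.tsv` holds the inferred curve and derivatives with
pointwise sds on the prediction grid, and `fit_out/manifest.json` records
the optimized hyperparameters (here log₁₀ θ = [−0.32, −0.84, −3.11]: the
fitted noise variance 10⁻³·¹ matches the generating σ_m² = 9·10⁻⁴) and the
final negative log marginal likelihood.

The same steps are available from Python:

```python
from growthgp import (CovarianceSpec, mixed_noisy_curve,
                      optimize_hyperparameters, joint_posterior,
                      growth_statistics)

ds = mixed_noisy_curve(n_points=100, n_replicates=3, seed=11)
series = ds.timeseries  # pooled, log-transformed
spec = optimize_hyperparameters(series, CovarianceSpec.default("squared_exponential"), seed=1)
post = joint_posterior(spec, series, ds.times)
print(growth_statistics(post, n_samples=100, seed=1).to_frame())
```

`growthgp benchmark` scores the GP against a cubic smoothing spline on
synthetic mixtures with known derivatives (trimmed mean absolute deviation
of the inferred growth rate).

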