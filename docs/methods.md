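# Methods

## Model

A time series y_i at times x_i (pooled over replicates, so times may
repeat) is modelled as y_i = f(x_i) + ε_i, with f a zero-mean Gaussian
process with covariance k(x, x′; θ) and ε_i independent Gaussian noise.
For growth curves the fit is done on the natural log of the raw
measurements, so the first derivative of f is the specific growth rate and
the doubling time is ln 2 over the rate. Hyperparameters are estimated by
maximizing the Gaussian marginal likelihood of y under N(0, K + σ²D); no
latent-function point estimates are ever formed outside this marginal.

Derivatives are handled without any extra machinery beyond the kernel:
if f ~ GP then its derivatives g, h are GPs with cov(g(x), f(x′)) = ∂₁k,
cov(g, g) = ∂₁∂₂k, cov(h, h) = ∂₁²∂₂²k, and so on. The joint Gaussian of
(y, f*, g*, h*) at prediction times X* is assembled from these blocks and
conditioned on y, giving posterior means and the full joint covariance.
Prediction times need not coincide with data times (interpolation is part
of the model).

## Covariance families and hyperparameters

All hyperparameters live on a log₁₀ scale with uniform box priors; each
family has exactly three: two kernel parameters plus the measurement-noise
variance σ² (the third hyperparameter is the *variance* added to the
diagonal, i.e. σ² = 10^θ₂).

* squared exponential: k = a·exp(−e(x−x′)²/2), a = 10^θ₀ the amplitude of
  the latent function's variation, e = 10^θ₁ the flexibility (an inverse
  squared length-scale). Default box (growth curves): θ₀ ∈ [−5, 5],
  θ₁ ∈ [−6, 2], θ₂ ∈ [−5, 0].
* Matern ν = 5/2: k = a(1 + √5 r √e + (5/3) e r²)·exp(−√5 r √e) with
  r = |x−x′|; same box as the squared exponential. Its latent functions
  are only twice differentiable, so second-derivative inference is refused
  rather than approximated (mathematically k'''' still exists at zero lag,
  but the h process it defines is so rough that reporting it would be
  misleading; the refusal is a deliberate interface decision).
* neural network (arcsine): k = (2/π)·asin(2(b + w x x′)/√((1 + 2(b + w x²))
  (1 + 2(b + w x′²)))) with bias variance b = 10^θ₀ (sets the level the
  sigmoid-like functions start from) and weight variance w = 10^θ₁
  (flexibility). Default box: θ₀ ∈ [−1, 5], θ₁ ∈ [−4, −1], θ₂ ∈ [−6, 2].
  Its cross-derivatives are generated symbolically (chain rule on the
  arcsine form) and compiled once per process; the squared-exponential and
  Matern derivatives are hand-derived closed forms. Everything is validated
  against finite differences — no derivative is ever approximated
  numerically in production code.

Degenerate (equal) bounds pin a hyperparameter. A warning is logged when
an optimum sits on a non-degenerate bound, since then the box rather than
the data chose the value.

## Optimization and numerics

* Optimizer: L-BFGS-B on the log₁₀ parameters with analytic gradients of
  the negative log marginal likelihood (dNLL/dθ = ½tr((K⁻¹ − ααᵀ)∂K/∂θ),
  α = K⁻¹y), best of `n_restarts` (default 3) uniform random starts in the
  box. One start is usually enough; restarts guard against local optima.
* Factorizations: Cholesky with additive jitter escalating from 10⁻¹⁰ to
  10⁻⁴ of the mean diagonal scale (trace/n), then a conditioning error that
  names the offending θ. Posterior *sampling* instead falls back to an
  eigendecomposition with negative eigenvalues clipped to zero: posterior
  covariances are often singular to machine precision, and escalating
  jitter there would inflate the sampled variances.
* Pooled replicates need no special casing: repeated times duplicate rows
  of K, and the noise on the diagonal keeps the system well posed.
* Ties in the argmax of sampled growth rates break to the earliest time;
  samples whose maximum rate is non-positive leave lag and doubling time
  undefined and are excluded from those two statistics with a logged count.
* Reported errors are population standard deviations (ddof = 0) over
  statistic samples; ddof is configurable.

## Empirical noise model

When the noise magnitude visibly varies over an experiment, the
across-replicate sample variance (divisor r−1) at each time point is
smoothed along time with a Gaussian filter whose standard deviation is 10%
of the experiment duration by default (converted to samples via the median
time step; reflecting boundaries; a width of zero disables smoothing),
floored at 10⁻⁴ of its mean to avoid singular likelihoods, and normalized
to mean one. The identity in the likelihood is replaced by this relative
diagonal and σ² remains the single fitted constant, interpretable as the
mean noise variance. At least two replicates per time point are required;
estimation happens on the same (log) scale the GP is fit on.

## Synthetic benchmark

The generator produces the weighted Gompertz + Richards mixture in
Zwietering's reparameterization, in which the modelled quantity is the log
relative population ln(N/N₀), μ_m is the maximum slope (= maximum specific
growth rate), λ the lag and A the asymptote:

* Gompertz: y = A·exp(−exp(μ_m e/A(λ−t) + 1)), A = 1.1, μ_m = 0.6, λ = 2.3,
  weight 0.3;
* Richards: y = A·[1 + ν e^{1+ν} exp(μ_m/A(1+ν)^{1+1/ν}(λ−t))]^{−1/ν},
  A = 1.5, μ_m = 0.3, λ = 4.3, ν = 0.8, weight 0.7.

The mixture cannot be fit by either model alone but has a closed-form
derivative (peak specific growth rate ≈ 0.215). Noise is multiplicative
log-normal on the raw population — observed = exp(mixture)·exp(ε),
ε ~ N(0, σ_m²), σ_m = 0.03 — i.e. additive Gaussian on the log scale the
GP fits. Curves are sampled on an even grid over (0, 15) time units, which
covers lag through saturation for these λ; the grid span is a genuine free
choice and the benchmark ratio below is sensitive to it.

What the generator emulates: smooth sigmoidal growth, multiplicative
measurement noise, replicate pooling. What it does not: outliers,
non-Gaussian or autocorrelated noise, plate effects, evaporation drifts,
or measurement nonlinearity at high density — so passing benchmarks show
correctness of the inference, not robustness to every artefact of real
plate-reader data.

## Evaluation

The error score is the mean absolute deviation between inferred and exact
specific growth rate, dropping floor(0.05·n) points at each end (endpoint
effects otherwise dominate). The baseline is scipy's cubic smoothing
spline (FITPACK) fit to the log data with smoothing target s = nσ_m² —
the true noise variance, an advantage the GP does not get since it infers
σ². Note FITPACK's knot-limited spline is not the exact roughness-penalized
smoothing spline; fitted values agree well below the noise scale but
derivative error scores can differ by ~20%, and the cross-implementation
test is calibrated accordingly.

Benchmark behaviour computed by the suite and `scripts/acceptance.py`
(20 datasets per condition, sizes chosen to keep a full run in minutes on
one CPU):

* the GP error-score distribution tightens from n = 10 to n = 1000;
* at n = 1000 the spline's median error exceeds the GP's; the excess
  fluctuates noticeably between seeds at 20 datasets because the spline's
  score distribution is bimodal (FITPACK sometimes under-resolves the
  growth phase);
* the Matern 5/2 GP scores consistently *better* than the squared
  exponential on this mixture (median ratio ≈ 0.6–0.8): the stationary
  squared exponential's single length-scale must compromise between the
  dead-flat lag phase and the sharp take-off, inflating early-phase
  derivative error, which the rougher Matern prior avoids.

## Known limitations

* Maximum-of-derivative statistics inherit a smoothing bias: the GP's
  bandwidth rounds off sharp rate peaks, so the max growth rate is biased
  a few percent low at moderate n (≈11% at n ≈ 120 for the Gompertz test
  curve, ≈5% at n = 300, ≈2–5% at n ≥ 480). The reported sd quantifies
  sampling uncertainty only, not this bias.
* Dense Cholesky costs O(n³); a few thousand pooled points are fine, tens
  of thousands are not. No sparse approximations are provided.
* Noise is assumed Gaussian (or log-normal on the raw scale); the
  empirical profile relaxes time-constancy but not Gaussianity.
* Hyperparameter boxes matter when data are scarce; bound-saturation
  warnings should be taken seriously.
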