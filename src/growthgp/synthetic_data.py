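"""Synthetic growth curves with exact, closed-form derivatives.

The generator builds a weighted sum of a Gompertz and a Richards growth
model in Zwietering's reparameterization, where the modelled quantity is
the natural log of the relative population size, mu_m is the maximum slope
(i.e. the maximum specific growth rate), lambda the lag and A the
asymptote.  The mixture cannot be fit exactly by either model alone, yet
its specific growth rate — the time derivative of the log-population
mixture — is available in closed form, which makes it a clean benchmark
for non-parametric derivative inference.

Measurement noise is log-normal and multiplicative on the raw population:
observed = exp(mixture) * exp(eps) with eps ~ N(0, sigma_m^2) i.i.d., so
the log-transformed observations carry additive Gaussian noise of sd
sigma_m around the mixture, matching a GP fit to log data.

The default parameters (Gompertz A=1.1, mu_m=0.6, lambda=2.3, weight 0.3;
Richards A=1.5, mu_m=0.3, lambda=4.3, nu=0.8, weight 0.7; sigma_m=0.03)
define the benchmark conditions used throughout; the default time range
(0, 15) covers lag through saturation for these lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gp_core import TimeSeries

__all__ = [
    "GrowthModelParams",
    "DEFAULT_PARAMS",
    "DEFAULT_TIME_RANGE",
    "gompertz_curve",
    "richards_curve",
    "mixed_curve",
    "mixed_noisy_curve",
    "SyntheticGrowthData",
]

E = float(np.e)

DEFAULT_TIME_RANGE = (0.0, 15.0)


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the weighted Gompertz + Richards benchmark mixture."""

    gompertz_A: float = 1.1
    gompertz_mu_m: float = 0.6
    gompertz_lag: float = 2.3
    gompertz_weight: float = 0.3
    richards_A: float = 1.5
    richards_mu_m: float = 0.3
    richards_lag: float = 4.3
    richards_nu: float = 0.8
    richards_weight: float = 0.7
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if min(self.gompertz_A, self.gompertz_mu_m, self.richards_A,
               self.richards_mu_m, self.richards_nu) <= 0:
            raise ValueError("A, mu_m and nu must be positive")
        if min(self.gompertz_weight, self.richards_weight) < 0:
            raise ValueError("weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


DEFAULT_PARAMS = GrowthModelParams()


def gompertz_curve(times, A: float, mu_m: float, lag: float):
    """Zwietering Gompertz curve and its exact time derivative.

    y(t) = A exp(-exp(mu_m e / A (lag - t) + 1)), describing ln(N/N0); by
    construction mu_m is the curve's maximum slope and the tangent there
    crosses zero at t = lag.
    """
    t = np.asarray(times, dtype=float)
    z = mu_m * E / A * (lag - t) + 1.0
    with np.errstate(over="ignore", under="ignore"):
        inner = np.exp(z)
        y = A * np.exp(-inner)
        dy = y * inner * mu_m * E / A
    return y, np.where(np.isfinite(dy), dy, 0.0)


def richards_curve(times, A: float, mu_m: float, lag: float, nu: float):
    """Zwietering Richards curve and its exact time derivative.

    y(t) = A [1 + nu exp(1 + nu) exp(mu_m / A (1 + nu)^(1 + 1/nu)
    (lag - t))]^(-1/nu); nu = 1 recovers the logistic reparameterization.
    """
    t = np.asarray(times, dtype=float)
    b = mu_m / A * (1.0 + nu) ** (1.0 + 1.0 / nu)
    with np.errstate(over="ignore", under="ignore"):
        q = nu * np.exp(1.0 + nu) * np.exp(b * (lag - t))
        y = A * (1.0 + q) ** (-1.0 / nu)
        dy = (A * b / nu) * q * (1.0 + q) ** (-1.0 / nu - 1.0)
    return y, np.where(np.isfinite(dy), dy, 0.0)


def mixed_curve(params: GrowthModelParams, times):
    """Log-population mixture, its derivative (the exact specific growth rate).

    Returns (log_curve, growth_rate): the weighted sum of the two Zwietering
    curves (which model log population) and its time derivative.
    """
    yg, dg = gompertz_curve(times, params.gompertz_A, params.gompertz_mu_m,
                            params.gompertz_lag)
    yr, dr = richards_curve(times, params.richards_A, params.richards_mu_m,
                            params.richards_lag, params.richards_nu)
    log_curve = params.gompertz_weight * yg + params.richards_weight * yr
    rate = params.gompertz_weight * dg + params.richards_weight * dr
    return log_curve, rate


@dataclass
class SyntheticGrowthData:
    """One synthetic dataset: noisy observations plus the exact truth.

    ``observations`` are on the raw (population) scale; ``log_clean`` is
    the noise-free mixture on the log scale; ``growth_rate`` is the exact
    specific growth rate d ln(clean)/dt on ``times``.
    """

    times: np.ndarray
    observations: np.ndarray  # (n_times, n_replicates), raw scale
    log_clean: np.ndarray
    growth_rate: np.ndarray
    params: GrowthModelParams

    @property
    def clean(self) -> np.ndarray:
        """Noise-free curve on the raw (population) scale."""
        return np.exp(self.log_clean)

    @property
    def timeseries(self) -> TimeSeries:
        """Pooled, log-transformed observations ready for GP fitting."""
        return TimeSeries.pool(self.times, self.observations, log_transform=True)


def mixed_noisy_curve(
    params: GrowthModelParams = DEFAULT_PARAMS,
    n_points: int = 100,
    time_range: tuple[float, float] = DEFAULT_TIME_RANGE,
    seed: int | None = None,
    n_replicates: int = 1,
) -> SyntheticGrowthData:
    """Mixture curve on an even grid with multiplicative log-normal noise.

    observed = clean * exp(eps), eps ~ N(0, noise_sd^2), where clean is the
    raw-scale curve exp(mixture); equivalently the log observations are the
    mixture plus Gaussian noise.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.linspace(time_range[0], time_range[1], n_points)
    log_clean, rate = mixed_curve(params, times)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, params.noise_sd, size=(n_points, n_replicates))
    observations = np.exp(log_clean)[:, None] * np.exp(eps)
    return SyntheticGrowthData(
        times=times,
        observations=observations,
        log_clean=log_clean,
        growth_rate=rate,
        params=params,
    )
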