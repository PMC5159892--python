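"""Error scoring of derivative estimates and the smoothing-spline baseline.

The error score is the trimmed mean absolute deviation between an inferred
and an exact derivative, dropping 5% of the points at each end by default
so endpoint effects do not dominate.  The baseline is a cubic smoothing
spline fit to the log-transformed data with its smoothing target set from
the true noise variance (s = n sigma_m^2) — an advantage the GP does not
get, since it must infer the noise level itself; reports should read the
comparison with that in mind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .covariance import CovarianceSpec
from .gp_core import TimeSeries, joint_posterior, optimize_hyperparameters
from .synthetic_data import (
    DEFAULT_PARAMS,
    DEFAULT_TIME_RANGE,
    GrowthModelParams,
    mixed_noisy_curve,
)

__all__ = ["ErrorScore", "error_score", "spline_baseline", "benchmark", "BenchmarkResult"]


@dataclass(frozen=True)
class ErrorScore:
    """Trimmed mean absolute deviation and the per-end trim count."""

    value: float
    n_trimmed: int


def error_score(inferred, exact, trim_fraction: float = 0.05) -> ErrorScore:
    """Mean |inferred - exact| over the central indices.

    ``floor(trim_fraction * n)`` points are dropped at each end (half-open
    index window), so small n with the default fraction trims nothing.
    """
    inferred = np.asarray(inferred, dtype=float).ravel()
    exact = np.asarray(exact, dtype=float).ravel()
    if inferred.size != exact.size:
        raise ValueError("inferred and exact must have equal length")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    n = inferred.size
    k = int(np.floor(trim_fraction * n))
    if n - 2 * k <= 0:
        raise ValueError("trimming removed every point")
    return ErrorScore(
        value=float(np.mean(np.abs(inferred[k : n - k] - exact[k : n - k]))),
        n_trimmed=k,
    )


def spline_baseline(data: TimeSeries, smoothing: float) -> np.ndarray:
    """First derivative of a cubic smoothing spline, at the data times.

    ``smoothing`` is the residual-sum-of-squares target of
    :class:`scipy.interpolate.UnivariateSpline`.  Requires strictly
    increasing times (average pooled replicates first) and n >= 4.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    t, v = data.times, data.values
    if t.size < 4:
        raise ValueError("cubic spline needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            "spline baseline needs strictly increasing times; aggregate "
            "replicate measurements at repeated times first"
        )
    spline = UnivariateSpline(t, v, k=3, s=smoothing)
    return spline.derivative()(t)


@dataclass
class BenchmarkResult:
    """Per-dataset error scores and their medians by (n, method)."""

    table: pd.DataFrame

    @property
    def medians(self) -> pd.DataFrame:
        return (
            self.table.groupby(["n", "method"])["score"].median().unstack("method")
        )


def benchmark(
    n_datasets: int,
    n_points_list: list[int],
    seed: int | None = None,
    families: tuple[str, ...] = ("squared_exponential",),
    params: GrowthModelParams = DEFAULT_PARAMS,
    time_range: tuple[float, float] = DEFAULT_TIME_RANGE,
    trim_fraction: float = 0.05,
    n_restarts: int = 2,
) -> BenchmarkResult:
    """Score GP and spline growth-rate inference on synthetic mixtures.

    For each n in ``n_points_list``, generates ``n_datasets`` noisy
    Gompertz+Richards curves, infers the specific growth rate with a GP per
    covariance family (posterior mean of the first derivative, means only)
    and with the cubic smoothing spline (smoothing n * sigma_m^2), and
    scores both against the exact rate.  Rows: dataset_id, n, method,
    score.  Reproducible for a fixed seed.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    root = np.random.default_rng(seed)
    rows = []
    for n in n_points_list:
        for d in range(n_datasets):
            data_seed, opt_seed = root.integers(2 ** 31, size=2)
            ds = mixed_noisy_curve(
                params, n_points=n, time_range=time_range, seed=int(data_seed)
            )
            series = ds.timeseries
            spline_g = spline_baseline(series, smoothing=n * params.noise_sd ** 2)
            rows.append(
                {
                    "dataset_id": d,
                    "n": n,
                    "method": "spline",
                    "score": error_score(spline_g, ds.growth_rate, trim_fraction).value,
                }
            )
            for family in families:
                spec = optimize_hyperparameters(
                    series,
                    CovarianceSpec.default(family),
                    n_restarts=n_restarts,
                    seed=int(opt_seed),
                )
                post = joint_posterior(
                    spec, series, ds.times, max_order=1, include_covariance=False
                )
                rows.append(
                    {
                        "dataset_id": d,
                        "n": n,
                        "method": f"gp_{family}",
                        "score": error_score(
                            post.mean_g, ds.growth_rate, trim_fraction
                        ).value,
                    }
                )
    return BenchmarkResult(table=pd.DataFrame(rows))
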