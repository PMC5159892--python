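"""Growth-curve summary statistics with sampling-based error bars.

All statistics are defined on the natural-log scale of the measurement, so
the first derivative g = d ln y / dt is the specific growth rate.  For each
posterior sample (f, g) we compute

* the maximum specific growth rate: max_t g(t), with its time t*;
* the doubling time: ln 2 / max rate;
* the lag time: where the tangent to ln y at t* crosses the horizontal
  line through the initial log-measurement y0, i.e.
  lag = t* - (f(t*) - y0) / g(t*).

Repeating over many samples of the joint posterior yields a distribution
for each statistic; its mean and standard deviation are reported as the
estimate and its error.  Samples whose maximum rate is non-positive (no
growth) leave lag and doubling time undefined and are excluded from those
two statistics, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp_core import JointPosterior, sample_posterior

__all__ = ["GrowthStatistics", "statistics_from_samples", "growth_statistics"]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class GrowthStatistics:
    """(mean, sd) pairs for each growth statistic, over posterior samples."""

    max_growth_rate: tuple[float, float]
    time_of_max: tuple[float, float]
    lag_time: tuple[float, float]
    doubling_time: tuple[float, float]
    n_samples: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (mean, sd) in (
            ("max_growth_rate", self.max_growth_rate),
            ("time_of_max", self.time_of_max),
            ("lag_time", self.lag_time),
            ("doubling_time", self.doubling_time),
        ):
            rows.append(
                {
                    "statistic": name,
                    "mean": mean,
                    "sd": sd,
                    "n_samples": self.n_samples,
                    "n_excluded": self.n_excluded,
                }
            )
        return pd.DataFrame(rows)


def _mean_sd(x: np.ndarray, ddof: int) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    if x.size <= ddof:
        return float(np.mean(x)), float("nan")
    return float(np.mean(x)), float(np.std(x, ddof=ddof))


def statistics_from_samples(
    samples: np.ndarray, times, y0_log: float, ddof: int = 0
) -> GrowthStatistics:
    """Growth statistics from joint (f, g, ...) posterior samples.

    ``samples`` has shape (n_samples, n_blocks >= 2, n_times): block 0 is
    the latent log-curve f, block 1 its derivative g.  Ties in the argmax
    of g break to the earliest time.  ``ddof=0`` (population sd) is the
    default convention for the reported errors.
    """
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float).ravel()
    if samples.ndim != 3 or samples.shape[1] < 2:
        raise ValueError("samples must have shape (n_samples, >=2 blocks, n_times)")
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate errors")
    if samples.shape[2] != times.size:
        raise ValueError("samples and times disagree on the number of time points")

    f, g = samples[:, 0, :], samples[:, 1, :]
    idx = np.argmax(g, axis=1)  # first index on ties
    rows = np.arange(samples.shape[0])
    rate = g[rows, idx]
    t_star = times[idx]
    f_star = f[rows, idx]

    valid = rate > 0
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        logger.warning(
            "%d of %d posterior samples had non-positive maximum growth rate; "
            "lag and doubling time exclude them",
            n_excluded,
            samples.shape[0],
        )
    lag = t_star[valid] - (f_star[valid] - y0_log) / rate[valid]
    doubling = LN2 / rate[valid]

    return GrowthStatistics(
        max_growth_rate=_mean_sd(rate, ddof),
        time_of_max=_mean_sd(t_star, ddof),
        lag_time=_mean_sd(lag, ddof),
        doubling_time=_mean_sd(doubling, ddof),
        n_samples=samples.shape[0],
        n_excluded=n_excluded,
    )


def growth_statistics(
    post: JointPosterior,
    n_samples: int = 100,
    seed: int | None = None,
    y0_log: float | None = None,
    ddof: int = 0,
) -> GrowthStatistics:
    """Sample the joint posterior and summarize the growth statistics.

    ``y0_log`` defaults to the posterior mean of f at the earliest
    prediction time, which is robust to a noisy first observation.
    """
    if post.mean_g is None:
        raise ValueError("posterior lacks a first-derivative block")
    if y0_log is None:
        y0_log = float(post.mean_f[np.argmin(post.prediction_times)])
    samples = sample_posterior(post, n_samples, seed=seed)
    return statistics_from_samples(samples, post.prediction_times, y0_log, ddof=ddof)
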