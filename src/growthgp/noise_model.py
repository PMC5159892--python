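"""Measurement-noise models for the marginal likelihood and posterior.

The default assumption is independent Gaussian noise with a constant
variance sigma^2 (itself a hyperparameter, optimized with the kernel
parameters).  When the noise magnitude visibly changes over the course of
an experiment — plate-reader optical densities are often noisiest at low
density — the relative profile can be estimated empirically from
replicates: the across-replicate variance at each time point, smoothed
along time with a Gaussian filter whose width is a fraction (default 10%)
of the experiment's duration.  The identity matrix in the likelihood is
then replaced by a diagonal of this relative scale, and sigma^2 remains
the single fitted constant multiplying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import NoiseEstimationError, ReplicateCountError

__all__ = ["NoiseModel", "replicate_variance", "estimate_relative_noise"]

#: Relative floor applied to the smoothed variance profile, as a fraction of
#: its mean, so an accidentally quiet time point cannot make the likelihood
#: singular.
VARIANCE_FLOOR_FRACTION = 1e-4


@dataclass
class NoiseModel:
    """Constant noise, or a per-time relative variance profile.

    For the empirical kind, ``relative_scale`` is normalized to mean 1 over
    the unique time points, so the fitted constant sigma^2 keeps its
    interpretation as a mean noise variance.
    """

    kind: str = "constant"
    times: np.ndarray | None = None
    relative_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "empirical"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "empirical":
            if self.times is None or self.relative_scale is None:
                raise ValueError("empirical noise needs times and relative_scale")
            self.times = np.asarray(self.times, dtype=float).ravel()
            self.relative_scale = np.asarray(self.relative_scale, dtype=float).ravel()
            if self.times.size != self.relative_scale.size:
                raise ValueError("times and relative_scale must match in length")
            if np.any(self.relative_scale < 0) or not np.any(self.relative_scale > 0):
                raise ValueError("relative_scale must be >= 0 with some entry > 0")

    @classmethod
    def constant(cls) -> "NoiseModel":
        return cls(kind="constant")

    def relative_diagonal(self, query_times) -> np.ndarray:
        """Relative noise variance at each (pooled) query time."""
        query_times = np.asarray(query_times, dtype=float).ravel()
        if self.kind == "constant":
            return np.ones(query_times.size)
        return np.interp(query_times, self.times, self.relative_scale)


def replicate_variance(data) -> tuple[np.ndarray, np.ndarray]:
    """Across-replicate sample variance (ddof=1) at each unique time point."""
    times = np.asarray(data.times, dtype=float)
    values = np.asarray(data.values, dtype=float)
    unique, inverse, counts = np.unique(times, return_inverse=True, return_counts=True)
    if np.any(counts < 2):
        raise ReplicateCountError(
            "empirical noise estimation needs >= 2 replicates at every time "
            "point; use constant noise for single-replicate data"
        )
    sums = np.bincount(inverse, weights=values)
    means = sums / counts
    sq = np.bincount(inverse, weights=(values - means[inverse]) ** 2)
    return unique, sq / (counts - 1)


def estimate_relative_noise(data, filter_width_fraction: float = 0.10) -> NoiseModel:
    """Empirical relative noise profile from replicate scatter.

    The per-time variance is smoothed with a Gaussian filter of standard
    deviation ``filter_width_fraction`` times the total duration (converted
    to samples via the median time step; reflecting boundaries), floored at
    a small fraction of its mean, and normalized to mean 1.  Zero width
    skips the smoothing entirely.
    """
    if not 0 <= filter_width_fraction < 1:
        raise ValueError("filter_width_fraction must lie in [0, 1)")
    unique, var = replicate_variance(data)
    if not np.any(var > 0):
        raise NoiseEstimationError(
            "replicates are identical at every time point: the relative "
            "noise profile is degenerate; use constant noise"
        )
    if filter_width_fraction > 0 and unique.size > 1:
        span = unique[-1] - unique[0]
        step = np.median(np.diff(unique))
        sigma_samples = filter_width_fraction * span / step
        var = ndimage.gaussian_filter1d(var, sigma=sigma_samples, mode="reflect")
    var = np.maximum(var, VARIANCE_FLOOR_FRACTION * var.mean())
    return NoiseModel(kind="empirical", times=unique, relative_scale=var / var.mean())
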