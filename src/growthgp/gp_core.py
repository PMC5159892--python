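"""Gaussian-process regression with joint inference of time derivatives.

The model: observations y_i = f(x_i) + eps_i with f drawn from a zero-mean
GP with covariance k(x, x'; theta) and eps_i independent Gaussian noise
(constant variance, or a fitted constant times an empirically estimated
per-time relative scale; see :mod:`growthgp.noise_model`).  Hyperparameters
are chosen by maximizing the marginal likelihood

    log P(y | theta, X) = -1/2 y^T (K + Sigma)^-1 y
                          - 1/2 log det(K + Sigma) - n/2 log 2 pi,

with bounded quasi-Newton (L-BFGS-B) runs from random starts inside the
log10 hyperparameter box.  Because derivatives of a GP are again GPs, the
joint distribution of y with the latent function f*, its first derivative
g* and second derivative h* at prediction points is Gaussian, built from
the analytic kernel cross-derivatives; conditioning on y gives the joint
posterior, and sampling from it propagates the full inference uncertainty
into any downstream summary statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from . import covariance as cov
from .covariance import CovarianceSpec
from .exceptions import (
    NumericalConditioningError,
    OptimizationFailureError,
)
from .noise_model import NoiseModel

__all__ = [
    "TimeSeries",
    "JointPosterior",
    "negative_log_marginal_likelihood",
    "nll_and_gradient",
    "optimize_hyperparameters",
    "joint_posterior",
    "sample_posterior",
]

logger = logging.getLogger(__name__)

_LOG10 = np.log(10.0)
_JITTER_START = 1e-10
_JITTER_MAX = 1e-4


@dataclass
class TimeSeries:
    """Pooled observations: times (sorted, possibly repeated) and values.

    Replicates are combined by simply pooling all points, so a time appears
    once per replicate measured there.  ``transformed`` records whether the
    values are natural logs of the raw measurements (the scale on which
    specific growth rates are defined).
    """

    times: np.ndarray
    values: np.ndarray
    replicate_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    transformed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 2:
            raise ValueError("need at least 2 observations")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted (non-decreasing)")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.times.size, dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id, dtype=int).ravel()
            if self.replicate_id.size != self.times.size:
                raise ValueError("replicate_id must match times in length")

    @property
    def n(self) -> int:
        return self.times.size

    @classmethod
    def pool(cls, times, values, log_transform: bool = False) -> "TimeSeries":
        """Pool an (n_times, n_replicates) value matrix into one series.

        The result is stably sorted by time, so replicate order is preserved
        within each time point.
        """
        times = np.asarray(times, dtype=float).ravel()
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.shape[0] != times.size:
            raise ValueError("values must have one row per time point")
        n_rep = values.shape[1]
        t = np.repeat(times, n_rep)
        v = values.ravel()
        rep = np.tile(np.arange(n_rep), times.size)
        if log_transform:
            if np.any(v <= 0):
                raise ValueError("log transform requires strictly positive values")
            v = np.log(v)
        order = np.argsort(t, kind="stable")
        return cls(t[order], v[order], rep[order], transformed=log_transform)


@dataclass
class JointPosterior:
    """Posterior over (f*, g*, h*) at the prediction times.

    ``cov_blocks`` is the full joint covariance over the concatenated
    vector (f*, g*, h*) — or (f*, g*) when the covariance family does not
    support second derivatives — and may be None when only means were
    requested.  The diagonals of the g and h blocks are the pointwise
    error bars on the inferred first and second derivatives.
    """

    prediction_times: np.ndarray
    mean_f: np.ndarray
    mean_g: np.ndarray | None = None
    mean_h: np.ndarray | None = None
    cov_blocks: np.ndarray | None = None

    @property
    def n_blocks(self) -> int:
        return 1 + (self.mean_g is not None) + (self.mean_h is not None)

    def _block_var(self, b: int) -> np.ndarray:
        if self.cov_blocks is None:
            raise ValueError("posterior was computed without covariance blocks")
        m = self.prediction_times.size
        d = np.diag(self.cov_blocks)[b * m : (b + 1) * m]
        return np.maximum(d, 0.0)

    @property
    def var_f(self) -> np.ndarray:
        return self._block_var(0)

    @property
    def var_g(self) -> np.ndarray:
        if self.mean_g is None:
            raise ValueError("no first-derivative block in this posterior")
        return self._block_var(1)

    @property
    def var_h(self) -> np.ndarray:
        if self.mean_h is None:
            raise ValueError("no second-derivative block in this posterior")
        return self._block_var(2)

    def stacked_mean(self) -> np.ndarray:
        parts = [self.mean_f]
        if self.mean_g is not None:
            parts.append(self.mean_g)
        if self.mean_h is not None:
            parts.append(self.mean_h)
        return np.concatenate(parts)


def _cholesky_with_jitter(A: np.ndarray, context: str) -> np.ndarray:
    """Lower Cholesky factor, escalating a trace-scaled jitter on failure."""
    n = A.shape[0]
    scale = np.trace(A) / n if n else 1.0
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    jitter = 0.0
    while True:
        try:
            return linalg.cholesky(A + jitter * np.eye(n), lower=True)
        except linalg.LinAlgError:
            jitter = _JITTER_START * scale if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX * scale:
                raise NumericalConditioningError(
                    f"Cholesky factorization failed after jitter escalation ({context})"
                ) from None


def _psd_factor(A: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = A for a (numerically) PSD matrix.

    Posterior covariances are often singular to machine precision (e.g.
    after noiseless interpolation), and escalating jitter would inflate the
    sampled variances; instead, fall back to an eigendecomposition with
    negative eigenvalues clipped to zero, which is exact for the PSD part.
    """
    n = A.shape[0]
    scale = max(np.trace(A) / n, np.finfo(float).tiny)
    try:
        return linalg.cholesky(A + 1e-12 * scale * np.eye(n), lower=True)
    except linalg.LinAlgError:
        w, V = linalg.eigh(A)
        if w.min() < -1e-6 * scale * n:
            raise NumericalConditioningError(
                "posterior covariance has a significantly negative eigenvalue"
            ) from None
        return V * np.sqrt(np.clip(w, 0.0, None))


def _train_cholesky(spec: CovarianceSpec, data: TimeSeries, noise: NoiseModel):
    rel = noise.relative_diagonal(data.times)
    Ky = cov.kernel_matrix(spec, data.times) + np.diag(spec.noise_variance * rel)
    L = _cholesky_with_jitter(Ky, f"theta(log10)={spec.log10_params}")
    return L, rel


def negative_log_marginal_likelihood(
    spec: CovarianceSpec, data: TimeSeries, noise: NoiseModel | None = None
) -> float:
    """-log P(y | theta, X) for the Gaussian N(0, K + sigma^2 D)."""
    noise = noise or NoiseModel.constant()
    L, _ = _train_cholesky(spec, data, noise)
    alpha = linalg.cho_solve((L, True), data.values)
    return float(
        0.5 * data.values @ alpha
        + np.sum(np.log(np.diag(L)))
        + 0.5 * data.n * np.log(2.0 * np.pi)
    )


def nll_and_gradient(
    spec: CovarianceSpec, data: TimeSeries, noise: NoiseModel | None = None
):
    """NLL and its gradient with respect to the log10 hyperparameters.

    Uses d NLL/d theta = 1/2 tr((Kinv - alpha alpha^T) dK/d theta) with the
    analytic kernel-parameter gradients, then the chain rule onto log10.
    """
    noise = noise or NoiseModel.constant()
    L, rel = _train_cholesky(spec, data, noise)
    y = data.values
    alpha = linalg.cho_solve((L, True), y)
    nll = float(
        0.5 * y @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * data.n * np.log(2 * np.pi)
    )
    Kinv = linalg.cho_solve((L, True), np.eye(data.n))
    dKs = cov.kernel_param_gradients(spec, data.times)
    grad = np.empty(3)
    for i, dK in enumerate(dKs):
        grad[i] = 0.5 * (np.sum(Kinv * dK) - alpha @ dK @ alpha)
    # noise variance enters only the diagonal: dK/d sigma2 = diag(rel)
    grad[2] = 0.5 * (np.sum(np.diag(Kinv) * rel) - np.sum(alpha * alpha * rel))
    grad *= spec.params * _LOG10  # chain rule: d theta / d log10(theta)
    return nll, grad


def optimize_hyperparameters(
    data: TimeSeries,
    spec_template: CovarianceSpec,
    noise: NoiseModel | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    maxiter: int = 200,
) -> CovarianceSpec:
    """Best-of-``n_restarts`` bounded quasi-Newton maximum marginal likelihood.

    Starting points are drawn uniformly (in log10 space) within the bounds;
    one run is usually sufficient but multiple restarts guard against local
    maxima.  A warning is logged if the optimum sits on a non-degenerate
    bound, since saturated bounds mean the prior box, not the data, chose
    the value.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    noise = noise or NoiseModel.constant()
    rng = np.random.default_rng(seed)
    lo, hi = spec_template.lower_bounds, spec_template.upper_bounds
    bounds = list(zip(lo, hi))

    def objective(x):
        try:
            s = CovarianceSpec(spec_template.family, x, lo, hi)
            return nll_and_gradient(s, data, noise)
        except (NumericalConditioningError, FloatingPointError):
            return 1e25, np.zeros(3)

    best = None
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if np.isfinite(res.fun) and res.fun < 1e24:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise OptimizationFailureError(
            f"all {n_restarts} optimization restarts failed numerically "
            f"(family={spec_template.family})"
        )
    opt = CovarianceSpec(
        spec_template.family, np.clip(best.x, lo, hi), lo.copy(), hi.copy()
    )
    for i in opt.on_bounds():
        logger.warning(
            "hyperparameter %d optimized to a bound (log10 value %.3f in "
            "[%.3f, %.3f]); consider widening the box",
            i,
            opt.log10_params[i],
            lo[i],
            hi[i],
        )
    return opt


def joint_posterior(
    spec: CovarianceSpec,
    data: TimeSeries,
    prediction_times,
    noise: NoiseModel | None = None,
    max_order: int | None = None,
    include_covariance: bool = True,
) -> JointPosterior:
    """Posterior over (f*, g*, h*) given y, by Gaussian conditioning.

    ``max_order`` caps the highest derivative inferred (default: 2, or 1
    for the Matern family, whose latent functions are only twice
    differentiable).  ``prediction_times`` need not coincide with the data
    times — interpolation is part of the model.  With
    ``include_covariance=False`` only the posterior means are computed,
    which is much cheaper on dense grids.
    """
    noise = noise or NoiseModel.constant()
    Xs = np.asarray(prediction_times, dtype=float).ravel()
    family_max = cov.max_derivative_order(spec.family)
    if max_order is None:
        max_order = family_max
    if max_order > family_max:
        raise ValueError(
            f"{spec.family} supports derivatives only up to order {family_max}"
        )
    orders = range(max_order + 1)

    L, _ = _train_cholesky(spec, data, noise)
    alpha = linalg.cho_solve((L, True), data.values)
    # cross-covariance of y with each derivative block: d2^j k(X, X*)
    B = np.hstack(
        [cov.kernel_derivative_matrix(spec, data.times, Xs, 0, j) for j in orders]
    )
    mean = B.T @ alpha
    m = Xs.size
    means = [mean[b * m : (b + 1) * m] for b in range(max_order + 1)]

    cov_blocks = None
    if include_covariance:
        A = np.block(
            [
                [cov.kernel_derivative_matrix(spec, Xs, Xs, i, j) for j in orders]
                for i in orders
            ]
        )
        V = linalg.solve_triangular(L, B, lower=True)
        cov_blocks = A - V.T @ V
        cov_blocks = 0.5 * (cov_blocks + cov_blocks.T)

    return JointPosterior(
        prediction_times=Xs,
        mean_f=means[0],
        mean_g=means[1] if max_order >= 1 else None,
        mean_h=means[2] if max_order >= 2 else None,
        cov_blocks=cov_blocks,
    )


def sample_posterior(
    post: JointPosterior, n_samples: int, seed: int | None = None
) -> np.ndarray:
    """Draw joint (f*, g*, h*) samples; shape (n_samples, n_blocks, n*).

    Each sample is an internally consistent triple drawn from the full
    joint covariance, so statistics computed per sample (e.g. the lag time,
    which mixes f and g) propagate the correlations correctly.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if post.cov_blocks is None:
        raise ValueError("posterior has no covariance blocks; cannot sample")
    mean = post.stacked_mean()
    L = _psd_factor(post.cov_blocks)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, mean.size))
    flat = mean[None, :] + z @ L.T
    return flat.reshape(n_samples, post.n_blocks, post.prediction_times.size)
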