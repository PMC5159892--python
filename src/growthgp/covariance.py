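"""Covariance (kernel) functions and their analytic cross-derivatives.

A Gaussian process prior over a latent function f is specified by a
covariance function k(x, x').  Because differentiation is a linear
operation, the derivatives of f are themselves Gaussian processes whose
covariances are partial derivatives of k: cov(f'(x), f(x')) = d1 k,
cov(f'(x), f'(x')) = d1 d2 k, and so on, where d1 and d2 differentiate with
respect to the first and second argument.  This module provides three
covariance families and every cross-derivative up to second order in each
argument, as closed-form expressions (never finite differences), which is
what the joint (f, g, h) prior over a function and its first two time
derivatives is assembled from.

Each family has exactly three hyperparameters, handled throughout on a
log10 scale: two kernel parameters and the measurement-noise variance.
For the squared exponential they are the amplitude of the latent function's
variation, its flexibility (an inverse squared length-scale) and the noise;
for the Matern (nu = 5/2) the same; for the neural-network (arcsine) kernel
the bias variance (which sets the initial y-value the sigmoid-like latent
functions level off from), the input-weight variance (flexibility) and the
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, UnsupportedSmoothnessError

__all__ = [
    "FAMILIES",
    "DEFAULT_BOUNDS",
    "CovarianceSpec",
    "kernel_matrix",
    "kernel_derivative_matrix",
    "kernel_param_gradients",
    "max_derivative_order",
]

FAMILIES = ("squared_exponential", "matern_5_2", "neural_network")

#: Default hyperparameter boxes on the log10 scale, chosen for growth-curve
#: fitting: wide amplitude, flexibility up to fast dynamics, noise variance
#: bounded by 1 (log-scale optical densities rarely have more noise than
#: signal).  The neural-network box keeps the flexibility small, which suits
#: sigmoid-shaped curves.
DEFAULT_BOUNDS = {
    "squared_exponential": ((-5.0, 5.0), (-6.0, 2.0), (-5.0, 0.0)),
    "matern_5_2": ((-5.0, 5.0), (-6.0, 2.0), (-5.0, 0.0)),
    "neural_network": ((-1.0, 5.0), (-4.0, -1.0), (-6.0, 2.0)),
}

_BOUND_TOL = 1e-9


@dataclass
class CovarianceSpec:
    """A covariance family plus its three hyperparameters (log10 scale).

    ``log10_params[0:2]`` are the kernel parameters, ``log10_params[2]`` is
    the measurement-noise variance that enters the likelihood's diagonal.
    Degenerate (equal) bounds pin a hyperparameter to a fixed value.
    """

    family: str
    log10_params: np.ndarray
    lower_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown covariance family {self.family!r}; choose from {FAMILIES}"
            )
        if self.lower_bounds is None or self.upper_bounds is None:
            lo, hi = zip(*DEFAULT_BOUNDS[self.family])
            if self.lower_bounds is None:
                self.lower_bounds = np.array(lo, dtype=float)
            if self.upper_bounds is None:
                self.upper_bounds = np.array(hi, dtype=float)
        self.log10_params = np.asarray(self.log10_params, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        for name, v in (
            ("log10_params", self.log10_params),
            ("lower_bounds", self.lower_bounds),
            ("upper_bounds", self.upper_bounds),
        ):
            if v.shape != (3,):
                raise ConfigurationError(f"{name} must have exactly 3 entries")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ConfigurationError("lower_bounds must not exceed upper_bounds")
        if np.any(self.log10_params < self.lower_bounds - _BOUND_TOL) or np.any(
            self.log10_params > self.upper_bounds + _BOUND_TOL
        ):
            raise ConfigurationError(
                f"log10_params {self.log10_params} outside bounds "
                f"[{self.lower_bounds}, {self.upper_bounds}]"
            )

    @classmethod
    def default(cls, family: str, log10_params=None) -> "CovarianceSpec":
        """Spec with the default bounds; parameters default to the box midpoint."""
        if family not in FAMILIES:
            raise ConfigurationError(
                f"unknown covariance family {family!r}; choose from {FAMILIES}"
            )
        lo, hi = (np.array(v, dtype=float) for v in zip(*DEFAULT_BOUNDS[family]))
        if log10_params is None:
            log10_params = 0.5 * (lo + hi)
        return cls(family, np.asarray(log10_params, float), lo, hi)

    @property
    def params(self) -> np.ndarray:
        """Hyperparameters on the natural scale."""
        return 10.0 ** self.log10_params

    @property
    def noise_variance(self) -> float:
        """The measurement-noise variance sigma^2 (natural scale)."""
        return float(10.0 ** self.log10_params[2])

    def on_bounds(self, tol: float = 1e-6) -> list[int]:
        """Indices of non-degenerate hyperparameters lying on a bound."""
        out = []
        for i in range(3):
            lo, hi = self.lower_bounds[i], self.upper_bounds[i]
            if hi - lo <= _BOUND_TOL:
                continue
            if self.log10_params[i] - lo < tol or hi - self.log10_params[i] < tol:
                out.append(i)
        return out


def max_derivative_order(family: str) -> int:
    """Highest derivative of the latent function the family supports.

    The Matern nu=5/2 prior imposes latent functions that are only twice
    differentiable, so its second-derivative process is too rough to infer;
    we refuse rather than approximate it.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown covariance family {family!r}")
    return 1 if family == "matern_5_2" else 2


# -- squared exponential -----------------------------------------------------
# k(u) = a * exp(-e u^2 / 2) with u = x - x'; derivatives in u are
# Hermite-polynomial multiples of k.

def _se_du(m: int, a: float, e: float, u: np.ndarray) -> np.ndarray:
    phi = a * np.exp(-0.5 * e * u * u)
    if m == 0:
        return phi
    if m == 1:
        return -e * u * phi
    if m == 2:
        return e * (e * u * u - 1.0) * phi
    if m == 3:
        return e * e * u * (3.0 - e * u * u) * phi
    if m == 4:
        u2 = u * u
        return e * e * (3.0 - 6.0 * e * u2 + e * e * u2 * u2) * phi
    raise ValueError(f"unsupported derivative order {m}")


# -- Matern nu = 5/2 ---------------------------------------------------------
# k(u) = a (1 + c r + c^2 r^2 / 3) exp(-c r), r = |u|, c = sqrt(5 e).
# Closed-form u-derivatives up to third order exist everywhere (including
# r = 0); the fourth is where the nu=5/2 smoothness runs out.

def _matern_du(m: int, a: float, e: float, u: np.ndarray) -> np.ndarray:
    c = np.sqrt(5.0 * e)
    r = np.abs(u)
    E = np.exp(-c * r)
    if m == 0:
        return a * (1.0 + c * r + c * c * r * r / 3.0) * E
    if m == 1:
        return -(a * c * c / 3.0) * u * (1.0 + c * r) * E
    if m == 2:
        return -(a * c * c / 3.0) * (1.0 + c * r - c * c * r * r) * E
    if m == 3:
        return (a * c ** 4 / 3.0) * u * (3.0 - c * r) * E
    raise ValueError(f"unsupported derivative order {m}")


# -- neural network (arcsine) ------------------------------------------------
# k(x, x') = (2/pi) asin( 2 (b + w x x') / sqrt((1 + 2(b + w x^2))
#            (1 + 2(b + w x'^2))) ) with a bias-augmented input; b is the
# bias variance, w the input-weight variance.  The cross-derivatives are
# generated symbolically once (chain rule on the arcsine form) and cached
# as compiled numpy functions.

_NN_CACHE: dict = {}


def _nn_func(key):
    if key not in _NN_CACHE:
        import sympy as sp

        x, y = sp.symbols("x y", real=True)
        b, w = sp.symbols("b w", positive=True)
        kk = (2 / sp.pi) * sp.asin(
            2 * (b + w * x * y)
            / sp.sqrt((1 + 2 * (b + w * x ** 2)) * (1 + 2 * (b + w * y ** 2)))
        )
        if key in ("b", "w"):
            expr = sp.diff(kk, {"b": b, "w": w}[key])
        else:
            j, l = key
            expr = sp.diff(kk, x, j, y, l) if (j or l) else kk
        _NN_CACHE[key] = sp.lambdify((x, y, b, w), expr, modules="numpy")
    return _NN_CACHE[key]


def _nn_eval(key, b: float, w: float, X: np.ndarray, X2: np.ndarray) -> np.ndarray:
    f = _nn_func(key)
    out = f(X[:, None], X2[None, :], b, w)
    return np.broadcast_to(np.asarray(out, dtype=float), (X.size, X2.size)).copy()


# -- public matrix builders --------------------------------------------------

def _as_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float).ravel()
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError("time points must be finite")
    return X


def kernel_derivative_matrix(
    spec: CovarianceSpec, X, X2, order1: int = 0, order2: int = 0
) -> np.ndarray:
    """Matrix of d1^order1 d2^order2 k(x_i, x2_j) from closed forms.

    ``order1`` differentiates with respect to the first argument (rows) and
    ``order2`` with respect to the second (columns); each may be 0..2.  For
    a stationary kernel k(u) with u = x - x' this is (-1)^order2 times the
    (order1+order2)-th derivative of k in u.
    """
    if not (0 <= order1 <= 2 and 0 <= order2 <= 2):
        raise ValueError("derivative orders must lie in 0..2")
    X, X2 = _as_times(X), _as_times(X2)
    a, e, _ = spec.params
    if spec.family == "neural_network":
        return _nn_eval((order1, order2), a, e, X, X2)
    total = order1 + order2
    sign = -1.0 if order2 % 2 else 1.0
    U = X[:, None] - X2[None, :]
    if spec.family == "squared_exponential":
        return sign * _se_du(total, a, e, U)
    if spec.family == "matern_5_2":
        if order1 == 2 and order2 == 2:
            raise UnsupportedSmoothnessError(
                "matern_5_2 latent functions are only twice differentiable: "
                "the fourth cross-derivative needed for cov(h, h) is not "
                "available; use squared_exponential or neural_network for "
                "second-derivative inference"
            )
        return sign * _matern_du(total, a, e, U)
    raise ConfigurationError(f"unknown covariance family {spec.family!r}")


def kernel_matrix(spec: CovarianceSpec, X, X2=None) -> np.ndarray:
    """Covariance matrix K with K[i, j] = k(x_i, x2_j)."""
    if X2 is None:
        X2 = X
    return kernel_derivative_matrix(spec, X, X2, 0, 0)


def kernel_param_gradients(spec: CovarianceSpec, X) -> list[np.ndarray]:
    """[dK/d(param 0), dK/d(param 1)] on the natural scale, at K(X, X).

    Used by the marginal-likelihood gradient; the third hyperparameter (the
    noise variance) enters only the likelihood's diagonal and is handled by
    the caller.
    """
    X = _as_times(X)
    a, e, _ = spec.params
    if spec.family == "neural_network":
        return [_nn_eval("b", a, e, X, X), _nn_eval("w", a, e, X, X)]
    U = X[:, None] - X[None, :]
    if spec.family == "squared_exponential":
        K = _se_du(0, a, e, U)
        return [K / a, -0.5 * U * U * K]
    if spec.family == "matern_5_2":
        c = np.sqrt(5.0 * e)
        r = np.abs(U)
        E = np.exp(-c * r)
        K = a * (1.0 + c * r + c * c * r * r / 3.0) * E
        dk_dc = -(a * c / 3.0) * r * r * (1.0 + c * r) * E
        return [K / a, dk_dc * c / (2.0 * e)]
    raise ConfigurationError(f"unknown covariance family {spec.family!r}")
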