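"""Least-squares identification of autoregressive models.

The AR(p) model of a zero-mean stationary process is

    x(n) = sum_{k=1..p} a_k x(n-k) + w(n),

with white Gaussian innovations w of variance Sigma_W. Writing the model for
n = p+1..N in compact form X = Z A + W, the coefficients are estimated by
ordinary least squares, the innovation variance from the residual sum of
squares, and the parameter uncertainty by the classical regression formulas:

    Sigma_A  = Sigma_W (Z'Z)^{-1}        (covariance of the coefficients)
    Var(Sigma_W) = 2 Sigma_W^2 / N       (Gaussian innovations)

These estimated (co)variances are what the Monte Carlo resampling scheme
perturbs; the residuals are what the bootstrap scheme resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import IdentificationError
from .series import TimeSeries

__all__ = ["ARModel", "ARFit", "fit_ar", "select_order", "is_stable", "ar_poly_roots"]

# Residual variance below this fraction of the signal variance is treated as an
# exact (noiseless) fit: Sigma_W = 0 up to float rounding.
_DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class ARModel:
    """An AR(p) parameter set Theta = {A, Sigma_W} plus the sampling period."""

    coefficients: np.ndarray
    innovation_variance: float
    sampling_period: float = 1.0

    def __post_init__(self) -> None:
        coeff = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if coeff.ndim != 1 or coeff.size < 1:
            raise ValueError("coefficients must be a nonempty vector")
        if not np.all(np.isfinite(coeff)):
            raise ValueError("coefficients must be finite")
        if self.innovation_variance < 0:
            raise ValueError("innovation_variance must be nonnegative")
        if not (self.sampling_period > 0):
            raise ValueError("sampling_period must be positive")
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "innovation_variance", float(self.innovation_variance))
        object.__setattr__(self, "sampling_period", float(self.sampling_period))

    @property
    def order(self) -> int:
        return self.coefficients.size

    def poles(self) -> np.ndarray:
        """Roots of A(z) = 1 - sum a_k z^{-k}, i.e. of z^p - a_1 z^{p-1} - ... - a_p."""
        return ar_poly_roots(self.coefficients)

    def is_stable(self) -> bool:
        return is_stable(self.coefficients)


@dataclass(frozen=True)
class ARFit:
    """A fitted AR model together with its estimated parameter uncertainty."""

    model: ARModel
    coeff_covariance: np.ndarray
    innovation_variance_variance: float
    residuals: np.ndarray
    n_samples: int
    degenerate: bool = False
    series_mean: float = field(default=0.0, compare=False)

    @property
    def order(self) -> int:
        return self.model.order


def ar_poly_roots(coefficients: np.ndarray) -> np.ndarray:
    """Poles of the AR transfer function 1/A(z)."""
    coeff = np.atleast_1d(np.asarray(coefficients, dtype=float))
    return np.roots(np.concatenate(([1.0], -coeff)))


def is_stable(coefficients: np.ndarray) -> bool:
    """True iff every root of A(z) lies strictly inside the unit circle."""
    return bool(np.all(np.abs(ar_poly_roots(coefficients)) < 1.0))


def _design_matrices(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Regressor matrix Z (columns are lags 1..p) and target vector X for n = p+1..N."""
    n = x.size
    target = x[order:]
    regressors = np.column_stack([x[order - k : n - k] for k in range(1, order + 1)])
    return regressors, target


def fit_ar(series: TimeSeries, order: int) -> ARFit:
    """Identify an AR(p) model from one realization by ordinary least squares.

    The sample mean is removed before regression (the AR model assumes a
    zero-mean process; recorded R-R series are not).

    Raises
    ------
    IdentificationError
        If the normal equations are numerically singular (constant or
        otherwise degenerate series).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n = len(series)
    if n <= 2 * order + 1:
        raise ValueError(f"series too short for order {order}: N={n} <= 2p+1")

    x = series.centered()
    regressors, target = _design_matrices(x, order)
    gram = regressors.T @ regressors

    # Cholesky doubles as the singularity test: a rank-deficient or badly
    # conditioned Gram matrix (constant series, order >= N/2 pathologies) fails.
    try:
        chol = scipy.linalg.cho_factor(gram, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise IdentificationError(
            f"normal equations singular for order {order} (degenerate series?)"
        ) from exc
    if np.linalg.cond(gram) > 1.0 / np.finfo(float).eps:
        raise IdentificationError(f"normal equations ill-conditioned for order {order}")

    coeff = scipy.linalg.cho_solve(chol, regressors.T @ target)
    residuals = target - regressors @ coeff
    sigma_w = float(residuals @ residuals) / (n - order)

    signal_power = float(x @ x) / n
    degenerate = sigma_w <= _DEGENERATE_REL_TOL * max(signal_power, 1.0) or sigma_w == 0.0
    if degenerate:
        sigma_w = 0.0

    gram_inv = scipy.linalg.cho_solve(chol, np.eye(order))
    coeff_cov = sigma_w * 0.5 * (gram_inv + gram_inv.T)  # symmetrize rounding

    model = ARModel(coeff, sigma_w, series.sampling_period)
    return ARFit(
        model=model,
        coeff_covariance=coeff_cov,
        innovation_variance_variance=2.0 * sigma_w**2 / n,
        residuals=residuals,
        n_samples=n,
        degenerate=degenerate,
        series_mean=float(series.values.mean()),
    )


def select_order(series: TimeSeries, min_order: int = 5, max_order: int = 15) -> int:
    """Akaike-criterion order selection over [min_order, max_order].

    AIC(p) = N ln(Sigma_W(p)) + 2p, ties broken toward the smaller order.
    A degenerate fit (Sigma_W = 0) has AIC -inf and wins at the smallest such p.
    """
    if min_order < 1 or max_order < min_order:
        raise ValueError("need 1 <= min_order <= max_order")
    n = len(series)
    if n <= 2 * max_order + 1:
        raise ValueError(f"series too short for max_order {max_order}")

    best_order, best_aic = None, np.inf
    for p in range(min_order, max_order + 1):
        fit = fit_ar(series, p)
        if fit.model.innovation_variance == 0.0:
            # exact fit: AIC = -inf cannot be beaten, and larger orders on a
            # noiseless series would only make the regression singular
            return p
        aic = n * np.log(fit.model.innovation_variance) + 2 * p
        if aic < best_aic:
            best_order, best_aic = p, aic
    assert best_order is not None
    return best_order
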