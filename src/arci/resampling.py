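"""Empirical sampling distributions of AR indexes from a single recording.

Two resampling schemes perturb the fitted parameter set Theta-hat = {A, Sigma_W}:

* **Monte Carlo (MC)** — draw M parameter sets from the estimated Gaussian
  sampling distribution: coefficients from N(A-hat, Sigma_A-hat), innovation
  variance independently from N(Sigma_W-hat, 2 Sigma_W-hat^2 / N). Draws with
  nonpositive variance or unstable coefficients are rejected and redrawn.
* **Bootstrap (BS)** — resample the (mean-centered) model residuals with
  replacement, regenerate the series as X~ = Z A-hat + V on the original
  fixed regressor matrix, and re-estimate the parameters by the same
  least-squares formulas.

Each retained parameter set is mapped to the descriptive indexes, yielding the
empirical sampling distribution from which percentile confidence limits and
the two-recording difference test are read. All randomness flows from one
integer seed through named substreams, so the same fit + seed reproduce the
replicate set exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ar import ARFit, ARModel, _design_matrices
from .errors import DegenerateFitError, ResamplingError
from .series import TimeSeries
from .spectral import HF_BAND, LF_BAND, LF_TARGET, IndexSet

__all__ = [
    "ReplicateSet",
    "ConfidenceSummary",
    "DifferenceTestResult",
    "mc_replicates",
    "bs_replicates",
    "confidence_summary",
    "difference_test",
]

PERCENTILES = (5, 25, 50, 75, 95)

# A confidence summary built from fewer than this fraction of defined
# replicates is flagged unreliable (the index was often undefined).
MIN_DEFINED_FRACTION = 0.9


@dataclass(frozen=True)
class ReplicateSet:
    """M resampled parameter sets and their index values."""

    method: str  # "mc" | "bs"
    m_replicates: int
    parameter_sets: tuple[ARModel, ...]
    index_values: tuple[IndexSet, ...]
    seed: int
    n_rejected: int = 0  # MC only: invalid draws discarded

    def __post_init__(self) -> None:
        if not (len(self.parameter_sets) == len(self.index_values) == self.m_replicates):
            raise ValueError("replicate counts inconsistent")

    def index_array(self, name: str) -> np.ndarray:
        """Replicate values of one index ('f_lf' | 'p_lfhf' | 's_x'); NaN = undefined."""
        pos = {"f_lf": 0, "p_lfhf": 1, "s_x": 2}[name]
        return np.array([iv.as_tuple()[pos] for iv in self.index_values])


@dataclass(frozen=True)
class ConfidenceSummary:
    """Percentile confidence limits of one index's empirical distribution."""

    point_estimate: float
    percentiles: dict[int, float]
    n_defined: int
    n_total: int

    @property
    def reliable(self) -> bool:
        return self.n_defined >= MIN_DEFINED_FRACTION * self.n_total

    def interval(self, lo: int = 5, hi: int = 95) -> tuple[float, float]:
        return self.percentiles[lo], self.percentiles[hi]


@dataclass(frozen=True)
class DifferenceTestResult:
    """Percentile test of H0: the two estimates share the same index value."""

    alpha: float
    interval: tuple[float, float]  # percentile interval of the b - a differences
    significant: bool
    direction: str  # "increase" | "decrease" | "none"
    n_pairs: int


def _substream(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible child stream of the master seed.

    Uses a CRC of the label (not Python's randomized ``hash``) so the stream
    is identical across processes.
    """
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _models_and_indexes(
    coeffs: np.ndarray, sigma_w: np.ndarray, sampling_period: float
) -> tuple[tuple[ARModel, ...], tuple[IndexSet, ...]]:
    f_lf, p_lfhf, s_x = _kernels.batch_indexes(
        coeffs, sigma_w, sampling_period, LF_BAND, HF_BAND, LF_TARGET
    )
    models = tuple(
        ARModel(coeffs[i], sigma_w[i], sampling_period) for i in range(coeffs.shape[0])
    )
    indexes = tuple(
        IndexSet(
            f_lf=None if np.isnan(f_lf[i]) else float(f_lf[i]),
            p_lfhf=None if np.isnan(p_lfhf[i]) else float(p_lfhf[i]),
            s_x=float(s_x[i]),
        )
        for i in range(coeffs.shape[0])
    )
    return models, indexes


def mc_replicates(fit: ARFit, m: int = 1000, seed: int = 0) -> ReplicateSet:
    """Monte Carlo resampling of the AR parameter sampling distribution.

    Raises
    ------
    ResamplingError
        If more than half of the Gaussian draws are invalid (variance <= 0 or
        unstable coefficients) within a 20*m attempt cap — the fit is too
        close to instability for the Gaussian approximation.
    """
    if fit.degenerate or fit.model.innovation_variance <= 0:
        raise DegenerateFitError("cannot resample a degenerate fit (Sigma_W = 0)")
    if m < 1:
        raise ValueError("m must be >= 1")

    rng = _substream(seed, "mc-draws")
    p = fit.order
    sw_sd = float(np.sqrt(fit.innovation_variance_variance))

    kept_coeffs: list[np.ndarray] = []
    kept_sw: list[np.ndarray] = []
    kept, attempts, rejected = 0, 0, 0
    while kept < m:
        if attempts >= 20 * m:
            raise ResamplingError(
                f"MC rejection rate too high ({rejected}/{attempts} draws invalid): "
                "fit too close to instability for the Gaussian approximation"
            )
        chunk = min(m - kept + 64, 20 * m - attempts)
        coeffs = rng.multivariate_normal(
            fit.model.coefficients, fit.coeff_covariance, size=chunk, method="svd"
        )
        sigma_w = rng.normal(fit.model.innovation_variance, sw_sd, size=chunk)
        valid = (sigma_w > 0) & _kernels.batch_stable(coeffs)
        attempts += chunk
        rejected += int(chunk - valid.sum())
        kept_coeffs.append(coeffs[valid])
        kept_sw.append(sigma_w[valid])
        kept += int(valid.sum())
    if rejected > attempts / 2:
        raise ResamplingError(
            f"MC rejection rate too high ({rejected}/{attempts} draws invalid): "
            "fit too close to instability for the Gaussian approximation"
        )

    coeffs = np.concatenate(kept_coeffs)[:m].reshape(m, p)
    sigma_w = np.concatenate(kept_sw)[:m]
    models, indexes = _models_and_indexes(coeffs, sigma_w, fit.model.sampling_period)
    return ReplicateSet(
        method="mc",
        m_replicates=m,
        parameter_sets=models,
        index_values=indexes,
        seed=seed,
        n_rejected=rejected,
    )


def bs_replicates(
    fit: ARFit,
    series: TimeSeries,
    m: int = 1000,
    seed: int = 0,
    regenerate: bool = False,
) -> ReplicateSet:
    """Residual-bootstrap resampling: regenerate the series, re-estimate, re-index.

    By default the surrogate series is built on the original fixed regressor
    matrix (X~ = Z A-hat + V); with ``regenerate=True`` the series is instead
    rebuilt recursively from the resampled innovations and the lag matrix is
    reconstructed from it. Replicates whose re-estimated coefficients are
    unstable keep their parameters but have all indexes marked undefined.
    """
    if fit.degenerate or fit.model.innovation_variance <= 0:
        raise DegenerateFitError("cannot resample a degenerate fit (Sigma_W = 0)")
    if m < 1:
        raise ValueError("m must be >= 1")
    p, n = fit.order, fit.n_samples
    if fit.residuals.size < p + 2:
        raise ResamplingError(f"need at least p+2={p + 2} residuals, have {fit.residuals.size}")

    x = series.centered()
    regressors, _ = _design_matrices(x, p)
    a_hat = fit.model.coefficients
    resid = fit.residuals - fit.residuals.mean()

    rng = _substream(seed, "bs-resample")
    draw = rng.integers(0, resid.size, size=(m, resid.size))
    innovations = resid[draw]  # (m, N-p)

    if not regenerate:
        x_new = regressors @ a_hat + innovations  # (m, N-p), fixed design
        gram = regressors.T @ regressors
        coeffs = np.linalg.solve(gram, regressors.T @ x_new.T).T  # (m, p)
        resid_new = x_new - coeffs @ regressors.T
    else:
        # Recursive regeneration: prepend the original first p samples, run the
        # AR recursion on the resampled innovations, rebuild lags per replicate.
        import scipy.signal

        coeffs = np.empty((m, p))
        resid_new = np.empty((m, n - p))
        b, a = [1.0], np.concatenate(([1.0], -a_hat))
        for i in range(m):
            zi = scipy.signal.lfiltic(b, a, x[:p][::-1])
            xi, _ = scipy.signal.lfilter(b, a, innovations[i], zi=zi)
            full = np.concatenate([x[:p], xi])
            z_i, t_i = _design_matrices(full, p)
            coeffs[i] = np.linalg.solve(z_i.T @ z_i, z_i.T @ t_i)
            resid_new[i] = t_i - z_i @ coeffs[i]
    sigma_w = (resid_new**2).sum(axis=1) / (n - p)

    models, indexes = _models_and_indexes(coeffs, sigma_w, fit.model.sampling_period)
    return ReplicateSet(
        method="bs",
        m_replicates=m,
        parameter_sets=models,
        index_values=indexes,
        seed=seed,
    )


def confidence_summary(
    values: np.ndarray | list, point_estimate: float | None
) -> ConfidenceSummary:
    """Percentile confidence limits (5/25/50/75/95, linear interpolation) of an
    index's replicate distribution. Undefined entries (None/NaN) are dropped
    and reported through ``n_defined``."""
    arr = np.array(
        [np.nan if v is None else float(v) for v in np.asarray(values, dtype=object)],
        dtype=float,
    )
    defined = arr[np.isfinite(arr)]
    if defined.size == 0:
        raise ResamplingError("no defined replicate values to summarize")
    pct = np.percentile(defined, PERCENTILES)  # linear interpolation rule
    return ConfidenceSummary(
        point_estimate=np.nan if point_estimate is None else float(point_estimate),
        percentiles=dict(zip(PERCENTILES, map(float, pct))),
        n_defined=int(defined.size),
        n_total=int(arr.size),
    )


def difference_test(
    values_a: np.ndarray | list,
    values_b: np.ndarray | list,
    alpha: float = 0.05,
    seed: int = 0,
) -> DifferenceTestResult:
    """Percentile test of a difference between two single-recording estimates.

    The replicate values of the first estimate are randomly permuted (seeded)
    and subtracted element-wise from the second's (random pairing, not all
    MxM combinations). H0 (zero difference) is rejected at level ``alpha`` iff
    zero falls outside the [100*alpha/2, 100*(1-alpha/2)] percentile interval
    of the differences; a zero exactly on a boundary is not significant.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    a = np.array([np.nan if v is None else float(v) for v in np.asarray(values_a, dtype=object)])
    b = np.array([np.nan if v is None else float(v) for v in np.asarray(values_b, dtype=object)])
    if a.size != b.size:
        raise ValueError(f"replicate sets differ in length: {a.size} vs {b.size}")

    rng = _substream(seed, "diff-pairing")
    diffs = b - a[rng.permutation(a.size)]
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 10:
        raise ResamplingError(
            f"only {diffs.size} defined difference pairs (<10); test unreliable"
        )
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = bool(lo > 0 or hi < 0)
    direction = "increase" if lo > 0 else ("decrease" if hi < 0 else "none")
    return DifferenceTestResult(
        alpha=alpha,
        interval=(float(lo), float(hi)),
        significant=significant,
        direction=direction,
        n_pairs=int(diffs.size),
    )
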