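"""Benchmark process generators for validating the resampling schemes.

The reference process is a fifth-order AR model whose transfer function is
parameterized directly by its poles, emulating a 5-minute R-R interval series
with a mean heart period of 1 s: a real pole (slow VLF fluctuations), a
conjugate pair near 0.1 Hz (Mayer-wave LF oscillation) and a conjugate pair
near 0.25 Hz (respiratory HF oscillation). Variants add quadratic
nonlinearity, threshold switching between two linear regimes, or a sinusoidal
trend, to probe robustness to violations of the linear-stationary assumption.

The multiple-realizations "gold standard" generates many independent series
from the true process and fits/indexes each one — the empirical sampling
distribution that single-recording resampling schemes try to reproduce.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .ar import ARModel, fit_ar, is_stable
from .errors import ArciError, SimulationError, UnstableModelError
from .series import TimeSeries
from .spectral import compute_indexes, process_variance

__all__ = [
    "Pole",
    "PoleSpec",
    "SimulationConfig",
    "poles_to_coefficients",
    "benchmark_poles",
    "benchmark_model",
    "THRESHOLD_B_COEFFICIENTS",
    "simulate_linear",
    "simulate_squared",
    "simulate_threshold",
    "add_trend",
    "gold_standard",
    "IndexSamples",
]

#: Default burn-in: the slowest benchmark pole (modulus 0.92) needs ~a few
#: hundred samples for the transient to decay below float noise.
DEFAULT_BURN_IN = 1000

_EXPLOSION_THRESHOLD = 1e6


@dataclass(frozen=True)
class Pole:
    """One entry of a pole specification."""

    modulus: float
    frequency: float = 0.0  # cycles/sample in [0, 0.5]; ignored sign
    kind: str = "real-pole"  # "real-pole" | "conjugate-pair"

    def __post_init__(self) -> None:
        if not (0 <= self.modulus < 1):
            raise ValueError("pole modulus must be in [0, 1) for a stable process")
        if not (0 <= self.frequency <= 0.5):
            raise ValueError("pole frequency must be in [0, 0.5] cycles/sample")
        if self.kind not in ("real-pole", "conjugate-pair"):
            raise ValueError(f"unknown pole kind {self.kind!r}")


@dataclass(frozen=True)
class PoleSpec:
    """A transfer-function pole configuration; total degree = AR order."""

    entries: tuple[Pole, ...]

    @property
    def order(self) -> int:
        return sum(1 if e.kind == "real-pole" else 2 for e in self.entries)


def poles_to_coefficients(spec: PoleSpec) -> np.ndarray:
    """Expand the characteristic polynomial and return AR coefficients a_1..a_p.

    Real poles contribute (1 - rho z^-1); conjugate pairs contribute
    (1 - 2 rho cos(2 pi f) z^-1 + rho^2 z^-2). Under the convention
    A(z) = 1 - sum a_k z^-k, a_k is minus the z^-k polynomial coefficient.
    """
    roots: list[complex] = []
    for e in spec.entries:
        if e.kind == "real-pole":
            sign = -1.0 if e.frequency == 0.5 else 1.0
            roots.append(sign * e.modulus)
        else:
            z = e.modulus * np.exp(2j * np.pi * e.frequency)
            roots.extend([z, np.conj(z)])
    poly = np.poly(roots).real  # monic in z: z^p + c_1 z^{p-1} + ...
    return -poly[1:]


def benchmark_poles(
    rho_vlf: float = 0.65,
    rho_lf: float = 0.8,
    f_lf: float = 0.1,
    rho_hf: float = 0.92,
    f_hf: float = 0.25,
) -> PoleSpec:
    """The fifth-order HRV-like benchmark pole configuration (frequencies in
    cycles/sample = Hz at a 1 s mean heart period)."""
    return PoleSpec(
        entries=(
            Pole(rho_vlf, 0.0, "real-pole"),
            Pole(rho_lf, f_lf, "conjugate-pair"),
            Pole(rho_hf, f_hf, "conjugate-pair"),
        )
    )


def benchmark_model(
    innovation_variance: float = 1.0, sampling_period: float = 1.0, **pole_kwargs
) -> ARModel:
    """The benchmark AR(5) as an ARModel (a1=1.944, a3=2.062, a5=0.352 at 3 d.p.)."""
    return ARModel(
        poles_to_coefficients(benchmark_poles(**pole_kwargs)),
        innovation_variance,
        sampling_period,
    )


#: Second-regime coefficients of the threshold process (slower, more irregular
#: LF component at rho_LF = 0.4, f_LF = 0.07), as conventionally printed.
THRESHOLD_B_COEFFICIENTS = np.array([1.363, -1.470, 1.257, -0.528, 0.088])


def _rng(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _recursive_simulate(
    stepper, sigma_w: float, n: int, seed: int, burn_in: int, sampling_period: float,
    label: str,
) -> TimeSeries:
    """Shared sample-by-sample recursion with explosion monitoring.

    All simulators use this one kernel and the "sim" innovation substream, so
    a nonlinear/switching variant with its extra term disabled reproduces the
    linear simulator bit-for-bit under the same seed.
    """
    rng = _rng(seed, "sim")
    total = n + burn_in
    p = stepper.order
    w = rng.normal(0.0, np.sqrt(sigma_w), size=total)
    x = np.zeros(total + p)
    for i in range(total):
        j = p + i
        x[j] = stepper.step(x, j) + w[i]
        if abs(x[j]) > _EXPLOSION_THRESHOLD:
            raise SimulationError(
                f"trajectory exceeded {_EXPLOSION_THRESHOLD:g} at sample {i} (seed={seed})"
            )
    return TimeSeries(x[p + burn_in :], sampling_period, label=f"{label}(seed={seed})")


class _LinearStep:
    def __init__(self, coeffs: np.ndarray):
        self.rev = coeffs[::-1].copy()  # so coeffs @ lags == rev @ x[i-p:i]
        self.order = coeffs.size

    def step(self, x: np.ndarray, i: int) -> float:
        return float(self.rev @ x[i - self.order : i])


class _SquaredStep(_LinearStep):
    def __init__(self, coeffs: np.ndarray, beta: float):
        super().__init__(coeffs)
        self.beta = beta

    def step(self, x: np.ndarray, i: int) -> float:
        return super().step(x, i) + self.beta * (x[i - 1] ** 2 - x[i - 2] ** 2)


class _ThresholdStep:
    def __init__(self, coeff_a: np.ndarray, coeff_b: np.ndarray, gamma: float):
        self.rev_a = coeff_a[::-1].copy()
        self.rev_b = coeff_b[::-1].copy()
        self.gamma = gamma
        self.order = coeff_a.size
        self.n_regime_b = 0

    def step(self, x: np.ndarray, i: int) -> float:
        lags = x[i - self.order : i]
        if x[i - 1] <= self.gamma:
            return float(self.rev_a @ lags)
        self.n_regime_b += 1
        return float(self.rev_b @ lags)


def simulate_linear(
    model: ARModel, n: int, seed: int = 0, burn_in: int = DEFAULT_BURN_IN
) -> TimeSeries:
    """One realization of the AR process driven by Gaussian white innovations.

    Starts from a zero initial state and discards the first ``burn_in``
    samples so the output is (weakly) stationary.
    """
    if not model.is_stable():
        raise UnstableModelError("cannot simulate a stationary series from an unstable model")
    if n < 2:
        raise ValueError("n must be >= 2")
    return _recursive_simulate(
        _LinearStep(model.coefficients),
        model.innovation_variance, n, seed, burn_in, model.sampling_period, "linear",
    )


def simulate_squared(
    model: ARModel, beta: float, n: int, seed: int = 0, burn_in: int = DEFAULT_BURN_IN
) -> TimeSeries:
    """AR recursion with an added quadratic term
    beta * (x(n-1)^2 - x(n-2)^2); beta = 0 reproduces the linear simulator
    bit-for-bit under the same seed."""
    if not model.is_stable():
        raise UnstableModelError("base linear model must be stable")
    if model.order < 2:
        raise ValueError("squared nonlinearity needs order >= 2")
    stepper = (
        _LinearStep(model.coefficients)
        if beta == 0.0
        else _SquaredStep(model.coefficients, beta)
    )
    return _recursive_simulate(
        stepper, model.innovation_variance, n, seed, burn_in,
        model.sampling_period, f"squared(beta={beta})",
    )


def simulate_threshold(
    coeff_a: np.ndarray,
    coeff_b: np.ndarray | None = None,
    gamma_rel: float = 1.0,
    n: int = 300,
    seed: int = 0,
    innovation_variance: float = 1.0,
    burn_in: int = DEFAULT_BURN_IN,
    sampling_period: float = 1.0,
) -> TimeSeries:
    """Threshold AR process switching between two linear regimes.

    Regime a applies when x(n-1) <= gamma, regime b above; the threshold is
    gamma_rel times the a-regime process standard deviation. ``coeff_b``
    defaults to the slow-LF second regime (:data:`THRESHOLD_B_COEFFICIENTS`).
    """
    coeff_a = np.atleast_1d(np.asarray(coeff_a, dtype=float))
    coeff_b = (
        THRESHOLD_B_COEFFICIENTS.copy()
        if coeff_b is None
        else np.atleast_1d(np.asarray(coeff_b, dtype=float))
    )
    if coeff_a.size != coeff_b.size:
        raise ValueError("both regimes must have the same order")
    if not (is_stable(coeff_a) and is_stable(coeff_b)):
        raise UnstableModelError("both regime coefficient sets must be stable")
    if gamma_rel <= 0:
        raise ValueError("gamma_rel must be positive")
    sd_a = float(
        np.sqrt(process_variance(ARModel(coeff_a, innovation_variance, sampling_period)))
    )
    stepper = _ThresholdStep(coeff_a, coeff_b, gamma_rel * sd_a)
    return _recursive_simulate(
        stepper, innovation_variance, n, seed, burn_in, sampling_period,
        f"threshold(gamma_rel={gamma_rel})",
    )


def add_trend(
    series: TimeSeries,
    amplitude_rel: float,
    period_s: float,
    seed: int = 0,
    phase: float | None = None,
) -> TimeSeries:
    """Superimpose a sinusoidal trend (nonstationarity probe).

    Amplitude is ``amplitude_rel`` times the sample standard deviation of the
    input; the phase is drawn uniformly from the seeded stream unless given.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if phase is None:
        phase = float(_rng(seed, "trend-phase").uniform(0.0, 2.0 * np.pi))
    amp = amplitude_rel * float(series.values.std())
    t = np.arange(len(series)) * series.sampling_period
    out = series.values + amp * np.sin(2.0 * np.pi * t / period_s + phase)
    return TimeSeries(out, series.sampling_period, label=f"{series.label}+trend")


@dataclass(frozen=True)
class IndexSamples:
    """Per-index value sets over many realizations (NaN = undefined); the
    multiple-realizations gold standard."""

    f_lf: np.ndarray
    p_lfhf: np.ndarray
    s_x: np.ndarray
    n_failed: int = 0

    def values(self, name: str) -> np.ndarray:
        return getattr(self, name)


def gold_standard(
    model: ARModel,
    n: int,
    n_realizations: int = 1000,
    seed: int = 0,
    fit_order: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
) -> IndexSamples:
    """Index distributions over independent realizations of the true process.

    Each realization is simulated, fitted (at the true order unless
    ``fit_order`` overrides it) and mapped to the three indexes. Realizations
    whose fit fails are skipped and counted.
    """
    order = model.order if fit_order is None else fit_order
    child_seeds = np.random.SeedSequence(seed).generate_state(n_realizations) & 0x7FFFFFFF
    out = {"f_lf": [], "p_lfhf": [], "s_x": []}
    n_failed = 0
    for s in child_seeds:
        try:
            ts = simulate_linear(model, n, int(s), burn_in)
            idx = compute_indexes(fit_ar(ts, order).model)
        except ArciError:
            n_failed += 1
            continue
        f, r, sx = idx.as_tuple()
        out["f_lf"].append(f)
        out["p_lfhf"].append(r)
        out["s_x"].append(sx)
    return IndexSamples(
        f_lf=np.array(out["f_lf"]),
        p_lfhf=np.array(out["p_lfhf"]),
        s_x=np.array(out["s_x"]),
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """One generator configuration; exactly one mode is active per run.

    Flat key-value serializable (see ``to_dict``/``from_dict``); keys are the
    field names, with ``coefficients``/``alt_coefficients`` as comma-joined
    floats when written to text configs.
    """

    label: str = "benchmark"
    coefficients: tuple[float, ...] | None = None  # default: benchmark AR(5)
    innovation_variance: float = 1.0
    n_samples: int = 300
    burn_in: int = DEFAULT_BURN_IN
    sampling_period: float = 1.0
    mode: str = "linear"  # "linear" | "squared" | "threshold"
    beta: float = 0.0
    gamma_rel: float = 0.0
    alt_coefficients: tuple[float, ...] | None = None
    trend_amplitude_rel: float = 0.0
    trend_period_s: float = 600.0
    fit_order: int | None = None  # estimation order; None = true order

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "squared", "threshold"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")

    def model(self) -> ARModel:
        coeff = (
            poles_to_coefficients(benchmark_poles())
            if self.coefficients is None
            else np.asarray(self.coefficients, dtype=float)
        )
        return ARModel(coeff, self.innovation_variance, self.sampling_period)

    @property
    def estimation_order(self) -> int:
        return self.model().order if self.fit_order is None else self.fit_order

    def simulate(self, seed: int) -> TimeSeries:
        model = self.model()
        if self.mode == "linear":
            ts = simulate_linear(model, self.n_samples, seed, self.burn_in)
        elif self.mode == "squared":
            ts = simulate_squared(model, self.beta, self.n_samples, seed, self.burn_in)
        else:
            ts = simulate_threshold(
                model.coefficients,
                None if self.alt_coefficients is None else np.asarray(self.alt_coefficients),
                self.gamma_rel,
                self.n_samples,
                seed,
                self.innovation_variance,
                self.burn_in,
                self.sampling_period,
            )
        if self.trend_amplitude_rel > 0:
            ts = add_trend(ts, self.trend_amplitude_rel, self.trend_period_s, seed)
        return ts

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "innovation_variance": self.innovation_variance,
            "n_samples": self.n_samples,
            "burn_in": self.burn_in,
            "sampling_period": self.sampling_period,
            "mode": self.mode,
            "beta": self.beta,
            "gamma_rel": self.gamma_rel,
            "trend_amplitude_rel": self.trend_amplitude_rel,
            "trend_period_s": self.trend_period_s,
        }
        if self.coefficients is not None:
            d["coefficients"] = ",".join(f"{c:.12g}" for c in self.coefficients)
        if self.alt_coefficients is not None:
            d["alt_coefficients"] = ",".join(f"{c:.12g}" for c in self.alt_coefficients)
        if self.fit_order is not None:
            d["fit_order"] = self.fit_order
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("coefficients", "alt_coefficients"):
            if key in d and isinstance(d[key], str):
                d[key] = tuple(float(v) for v in d[key].split(","))
            elif key in d and d[key] is not None:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)
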