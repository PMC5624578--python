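"""AR power spectrum, pole-residue spectral decomposition, and derived indexes.

For a stable AR(p) model with coefficients a_k, innovation variance Sigma_W
and sampling period T, the power spectral density is

    P(f) = Sigma_W * T / |A(e^{j 2 pi f T})|^2,    A(z) = 1 - sum a_k z^{-k},

denominated per Hz so that the two-sided integral over [-1/2T, 1/2T] equals
the process variance Sigma_X. Each pole of 1/A(z) (real pole, or conjugate
pair taken together) contributes one oscillatory component with a central
frequency set by the pole phase and a power given by the residue of the
spectral density on the unit circle; the component powers sum exactly to
Sigma_X. Individual powers can be negative when poles interact — the values
are retained (conservation still holds) and a warning is emitted.

Three descriptive indexes of heart-rate variability are derived:

* ``f_LF`` — central frequency of the decomposition component in the LF band
  (default 0.04-0.15 Hz) nearest 0.1 Hz (the Mayer-wave peak);
* ``P_LFHF`` — ratio of LF-band to HF-band (default 0.15-0.4 Hz) component
  powers, the classical sympathovagal-balance marker;
* ``S_X`` — information storage (1/2) ln(Sigma_X / Sigma_W) in nats, the
  share of the present sample predictable from the past.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ar import ARModel
from .errors import DegenerateFitError, RepeatedPoleError, UnstableModelError

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "LF_TARGET",
    "SpectralComponent",
    "SpectralDecomposition",
    "IndexSet",
    "psd",
    "process_variance",
    "decompose",
    "information_storage",
    "lf_central_frequency",
    "lf_hf_ratio",
    "compute_indexes",
]

#: LF band [0.04, 0.15] Hz (closed) and HF band (0.15, 0.4] Hz (half-open).
LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.4)
#: The f_LF index is the LF-band component nearest this frequency (Hz).
LF_TARGET: float = 0.1


@dataclass(frozen=True)
class SpectralComponent:
    """One oscillatory component of the AR spectrum."""

    central_frequency: float  # Hz
    power: float  # signal units^2
    pole: complex  # representative pole (positive-phase member of a pair)
    kind: str  # "real-pole" | "conjugate-pair"


@dataclass(frozen=True)
class SpectralDecomposition:
    """The AR spectrum split into oscillatory components.

    ``total_variance`` is the model-implied process variance Sigma_X from the
    Yule-Walker route; the component powers come from the residue route and
    sum to it within numerical tolerance.
    """

    components: tuple[SpectralComponent, ...]
    total_variance: float
    model: ARModel


@dataclass(frozen=True)
class IndexSet:
    """The three descriptive indexes for one AR parameter set.

    ``f_lf`` and ``p_lfhf`` are ``None`` when the corresponding band holds no
    spectral component — an explicit undefined state, never an accidental NaN.
    """

    f_lf: float | None
    p_lfhf: float | None
    s_x: float

    def as_tuple(self) -> tuple[float, float, float]:
        """(f_lf, p_lfhf, s_x) with NaN standing in for undefined entries."""
        return (
            np.nan if self.f_lf is None else self.f_lf,
            np.nan if self.p_lfhf is None else self.p_lfhf,
            self.s_x,
        )


def _require_stable(model: ARModel) -> None:
    if not model.is_stable():
        raise UnstableModelError(
            "AR polynomial has roots on/outside the unit circle; "
            "stationary spectrum undefined"
        )


def psd(model: ARModel, n_freqs: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Sample P(f) on a uniform grid over [0, 1/(2T)].

    Returns ``(frequencies_hz, density)``. The density carries the sampling-
    period factor so that the two-sided integral equals Sigma_X.
    """
    _require_stable(model)
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    t = model.sampling_period
    freqs = np.linspace(0.0, 0.5 / t, n_freqs)
    z = np.exp(-2j * np.pi * freqs * t)
    a_of_z = np.ones_like(z)
    zk = np.ones_like(z)
    for ak in model.coefficients:
        zk = zk * z
        a_of_z = a_of_z - ak * zk
    density = model.innovation_variance * t / np.abs(a_of_z) ** 2
    return freqs, density


def process_variance(model: ARModel) -> float:
    """Model-implied process variance Sigma_X (Yule-Walker stationary solution)."""
    _require_stable(model)
    return float(
        _kernels.batch_process_variance(
            model.coefficients[None, :], np.array([model.innovation_variance])
        )[0]
    )


def decompose(model: ARModel) -> SpectralDecomposition:
    """Split the AR spectrum into one component per real pole / conjugate pair.

    Raises
    ------
    UnstableModelError
        If any pole lies on or outside the unit circle.
    RepeatedPoleError
        If two poles coincide within tolerance (the residue method assumes
        simple poles).
    """
    _require_stable(model)
    coeffs = model.coefficients[None, :]
    sw = np.array([model.innovation_variance])
    roots = _kernels.batch_roots(coeffs)

    r = roots[0]
    if r.size > 1:
        diff = np.abs(r[:, None] - r[None, :])
        np.fill_diagonal(diff, np.inf)
        if diff.min() < _kernels.REPEATED_POLE_TOL:
            raise RepeatedPoleError(
                f"poles closer than {_kernels.REPEATED_POLE_TOL} in the complex plane"
            )

    freqs, powers = _kernels.batch_components(coeffs, sw, model.sampling_period, roots)
    components = []
    for j in range(r.size):
        if not np.isfinite(freqs[0, j]):
            continue
        is_real = abs(r[j].imag) <= 1e-9 * max(abs(r[j]), 1.0)
        components.append(
            SpectralComponent(
                central_frequency=float(freqs[0, j]),
                power=float(powers[0, j]),
                pole=complex(r[j].real, 0.0) if is_real else complex(r[j]),
                kind="real-pole" if is_real else "conjugate-pair",
            )
        )
    components.sort(key=lambda c: c.central_frequency)
    if any(c.power < 0 for c in components):
        warnings.warn(
            "spectral decomposition produced a negative component power "
            "(interacting poles); power conservation still holds",
            stacklevel=2,
        )
    return SpectralDecomposition(
        components=tuple(components),
        total_variance=process_variance(model),
        model=model,
    )


def information_storage(model: ARModel) -> float:
    """S_X = (1/2) ln(Sigma_X / Sigma_W), in nats; nonnegative for stable models."""
    _require_stable(model)
    if model.innovation_variance <= 0:
        raise DegenerateFitError("Sigma_W = 0: information storage undefined")
    return 0.5 * float(np.log(process_variance(model) / model.innovation_variance))


def lf_central_frequency(
    decomp: SpectralDecomposition,
    lf_band: tuple[float, float] = LF_BAND,
    target: float = LF_TARGET,
) -> float | None:
    """Central frequency of the LF-band component nearest ``target``; None if the band is empty."""
    in_band = [
        c for c in decomp.components if lf_band[0] <= c.central_frequency <= lf_band[1]
    ]
    if not in_band:
        return None
    best = min(in_band, key=lambda c: abs(c.central_frequency - target))
    return best.central_frequency


def lf_hf_ratio(
    decomp: SpectralDecomposition,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> float | None:
    """Ratio of LF-band to HF-band component powers; None if either band holds
    no component. Negative residue powers are retained in the sums, so extreme
    parameter sets can yield a negative ratio — clipping those would distort
    the replicate distributions the percentile machinery reads."""
    lf = [c.power for c in decomp.components if lf_band[0] <= c.central_frequency <= lf_band[1]]
    hf = [c.power for c in decomp.components if hf_band[0] < c.central_frequency <= hf_band[1]]
    if not lf or not hf or sum(hf) == 0:
        return None
    return sum(lf) / sum(hf)


def compute_indexes(model: ARModel) -> IndexSet:
    """Bundle f_LF, P_LFHF and S_X (default bands) for one parameter set."""
    _require_stable(model)
    if model.innovation_variance <= 0:
        raise DegenerateFitError("Sigma_W = 0: indexes undefined")
    f_lf, p_lfhf, s_x = (
        float(v)
        for v in np.concatenate(
            _kernels.batch_indexes(
                model.coefficients[None, :],
                np.array([model.innovation_variance]),
                model.sampling_period,
                LF_BAND,
                HF_BAND,
                LF_TARGET,
            )
        )
    )
    return IndexSet(
        f_lf=None if np.isnan(f_lf) else f_lf,
        p_lfhf=None if np.isnan(p_lfhf) else p_lfhf,
        s_x=s_x,
    )
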