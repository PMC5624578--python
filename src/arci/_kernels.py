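"""Vectorized kernels shared by the scalar spectral API and the replicate engines.

Everything here operates on a *batch* of AR parameter sets: a coefficient
matrix of shape (M, p) and an innovation-variance vector of shape (M,). The
scalar operations in :mod:`arci.spectral` call these with M = 1, so point
estimates and resampled replicates go through bit-identical arithmetic.

Undefined quantities (no LF component, unstable model, ...) are NaN at this
layer; the public API converts them to explicit ``None`` states.
"""

from __future__ import annotations

import numpy as np

# Two poles closer than this in the complex plane break the simple-pole
# assumption of the residue decomposition.
REPEATED_POLE_TOL = 1e-8
# Imaginary parts below this are rounding noise on a real pole.
_REAL_POLE_TOL = 1e-9


def batch_roots(coeffs: np.ndarray) -> np.ndarray:
    """Poles of A(z) for each row of ``coeffs``: eigenvalues of stacked companion matrices."""
    coeffs = np.atleast_2d(coeffs)
    m, p = coeffs.shape
    if p == 1:
        return coeffs.astype(complex)
    comp = np.zeros((m, p, p))
    comp[:, 0, :] = coeffs
    idx = np.arange(p - 1)
    comp[:, idx + 1, idx] = 1.0
    return np.linalg.eigvals(comp)


def batch_stable(coeffs: np.ndarray, roots: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask: all poles strictly inside the unit circle."""
    if roots is None:
        roots = batch_roots(coeffs)
    return np.all(np.abs(roots) < 1.0, axis=1)


def batch_process_variance(coeffs: np.ndarray, sigma_w: np.ndarray) -> np.ndarray:
    """Model-implied process variance Sigma_X by the Yule-Walker system, per row.

    Solves for the stationary autocovariances r_0..r_p of each model:
        r_0 - sum_k a_k r_k        = Sigma_W
        r_j - sum_k a_k r_{|j-k|}  = 0        (j = 1..p)
    and returns r_0. Unstable rows yield meaningless values; callers mask them.
    """
    coeffs = np.atleast_2d(coeffs)
    sigma_w = np.atleast_1d(sigma_w).astype(float)
    m, p = coeffs.shape
    system = np.broadcast_to(np.eye(p + 1), (m, p + 1, p + 1)).copy()
    for j in range(p + 1):
        for k in range(1, p + 1):
            system[:, j, abs(j - k)] -= coeffs[:, k - 1]
    rhs = np.zeros((m, p + 1))
    rhs[:, 0] = sigma_w
    try:
        acov = np.linalg.solve(system, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # Singular rows (boundary-unstable draws): solve row-wise, NaN on failure.
        acov = np.full((m, p + 1), np.nan)
        for i in range(m):
            try:
                acov[i] = np.linalg.solve(system[i], rhs[i])
            except np.linalg.LinAlgError:
                pass
    return acov[:, 0]


def batch_residues(
    coeffs: np.ndarray, sigma_w: np.ndarray, roots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Residues of Sigma_W / (z A(z) A(1/z)) at each pole, per row.

    Returns ``(roots, residues)``, both of shape (M, p). The sum of residues
    over the poles of a stable model equals Sigma_X (contour integral of the
    spectral density over the unit circle), which is how the residue method
    splits the process variance into per-pole oscillatory components.
    """
    coeffs = np.atleast_2d(coeffs)
    sigma_w = np.atleast_1d(sigma_w).astype(float)
    m, p = coeffs.shape
    if roots is None:
        roots = batch_roots(coeffs)

    # a'(r_k) = prod_{j != k} (r_k - r_j) for the monic polynomial with these roots
    diff = roots[:, :, None] - roots[:, None, :]
    diff[:, np.arange(p), np.arange(p)] = 1.0
    aprime = np.prod(diff, axis=2)

    # B(z) = A(1/z) scaled: B(r) = 1 - sum_k a_k r^k
    powers = np.cumprod(np.repeat(roots[:, None, :], p, axis=1), axis=1)  # r^(i+1)
    b_at_roots = 1.0 - np.einsum("mk,mkj->mj", coeffs, powers)

    with np.errstate(divide="ignore", invalid="ignore"):
        residues = sigma_w[:, None] * roots ** (p - 1) / (aprime * b_at_roots)
    return roots, residues


def batch_components(
    coeffs: np.ndarray,
    sigma_w: np.ndarray,
    sampling_period: float,
    roots: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Central frequencies (Hz) and powers of the spectral components, per row.

    One entry per real pole and per conjugate pair (the pair's two residues are
    complex conjugates, so the pair power is twice the real part of one of
    them). Entries that do not correspond to a component (the negative-
    frequency member of each pair) are NaN. Frequencies: 0 for real positive
    poles, Nyquist for real negative poles, pole phase / (2 pi T) otherwise.
    """
    roots, residues = batch_residues(coeffs, sigma_w, roots)
    m, p = roots.shape
    nyquist = 0.5 / sampling_period

    is_real = np.abs(roots.imag) <= _REAL_POLE_TOL * np.maximum(np.abs(roots), 1.0)
    is_pair_rep = ~is_real & (roots.imag > 0)

    freqs = np.full((m, p), np.nan)
    powers = np.full((m, p), np.nan)

    freqs[is_real] = np.where(roots.real[is_real] >= 0, 0.0, nyquist)
    powers[is_real] = residues.real[is_real]

    phase = np.abs(np.angle(roots))
    freqs[is_pair_rep] = phase[is_pair_rep] / (2.0 * np.pi * sampling_period)
    powers[is_pair_rep] = 2.0 * residues.real[is_pair_rep]
    return freqs, powers


def batch_indexes(
    coeffs: np.ndarray,
    sigma_w: np.ndarray,
    sampling_period: float,
    lf_band: tuple[float, float],
    hf_band: tuple[float, float],
    lf_target: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """f_LF, P_LFHF and S_X for each parameter set; NaN where undefined.

    Unstable rows get NaN for all three indexes. Band membership: LF closed
    [lo, hi], HF half-open (lo, hi]; components above the HF upper edge are
    outside both bands. A nonpositive band power sum leaves the ratio
    undefined (the residue method can produce negative component powers).
    """
    coeffs = np.atleast_2d(coeffs)
    sigma_w = np.atleast_1d(sigma_w).astype(float)
    m = coeffs.shape[0]
    roots = batch_roots(coeffs)
    stable = batch_stable(coeffs, roots)

    sigma_x = batch_process_variance(coeffs, sigma_w)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_x = 0.5 * np.log(sigma_x / sigma_w)
    s_x = np.where(stable & (sigma_w > 0) & (sigma_x > 0), s_x, np.nan)

    freqs, powers = batch_components(coeffs, sigma_w, sampling_period, roots)
    defined = np.isfinite(freqs) & np.isfinite(powers) & stable[:, None]
    in_lf = defined & (freqs >= lf_band[0]) & (freqs <= lf_band[1])
    in_hf = defined & (freqs > hf_band[0]) & (freqs <= hf_band[1])

    # f_LF: among LF-band components, the one nearest the target frequency
    dist = np.where(in_lf, np.abs(freqs - lf_target), np.inf)
    nearest = np.argmin(dist, axis=1)
    has_lf = in_lf.any(axis=1)
    f_lf = np.where(has_lf, freqs[np.arange(m), nearest], np.nan)

    # The ratio is the plain quotient of band sums whenever both bands hold a
    # component; residue powers can be negative in the tails of the replicate
    # distribution, and those values are retained (clipping them would
    # truncate the empirical distribution the percentile test reads).
    lf_power = np.where(in_lf, powers, 0.0).sum(axis=1)
    hf_power = np.where(in_hf, powers, 0.0).sum(axis=1)
    ratio_ok = has_lf & in_hf.any(axis=1) & (hf_power != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_lfhf = np.where(ratio_ok, lf_power / hf_power, np.nan)

    return f_lf, p_lfhf, s_x
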