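# Methods

## Model and estimation

The observed series is treated as a realization of a stationary, linear,
Gaussian AR(p) process. `fit_ar` removes the sample mean before regression
(the AR equations assume a zero-mean process; recorded R-R series are not),
builds the lag matrix Z for rows n = p+1..N, and solves the normal equations
through a Cholesky factorization of ZᵀZ — never an explicit inverse. A Gram
matrix that fails the factorization or whose condition number exceeds the
reciprocal machine epsilon raises an identification error (constant or
otherwise degenerate input). The estimates are

* Â = (ZᵀZ)⁻¹ZᵀX (coefficients),
* Σ̂_W = (N−p)⁻¹ Σ ŵ(n)² (innovation variance),
* Σ̂_A = Σ̂_W (ZᵀZ)⁻¹ (coefficient covariance),
* Var(Σ̂_Σ_W) = 2Σ̂_W²/N (Gaussian innovations).

A residual variance below 10⁻¹² of the signal power marks the fit
*degenerate* (an exact, noiseless recursion): Σ̂_W is set to zero and all
downstream indexes refuse to evaluate rather than emit infinities.

Order selection uses AIC(p) = N·ln Σ̂_W(p) + 2p over a configurable range
(default 5–15 for recorded R-R series), ties broken toward the smaller
order; a degenerate fit (AIC = −∞) ends the scan at the smallest exact
order. AIC retains its fixed asymptotic overfit probability (≈16% per extra
order); the package makes no attempt to "fix" this, since overfitting is
benign for the resampling machinery while underfitting is not (see the
order-mismatch study).

## Spectrum, decomposition, indexes

The spectral density is written per Hz, P(f) = Σ_W·T/|A(e^{j2πfT})|², so
that its two-sided integral over [−1/(2T), 1/(2T)] equals the process
variance; with T = 1 s (all simulations) this coincides with the
conventional form without the T factor. For recorded R-R series T is the
mean R-R interval in seconds, mapping beat-domain frequencies to Hz.

Σ_X is always the **model-implied** variance, obtained from the
(p+1)-dimensional Yule-Walker linear system in the stationary
autocovariances. Replicated parameter sets have no data attached, so a
sample variance is not an option there; using the model-implied value
everywhere keeps point estimates and replicates on the same footing.
`statsmodels.arma_acovf` serves as an independent oracle in the tests, not
as the implementation.

The decomposition follows the pole-residue method: with ā(z) = z^p·A(z) and
poles r_k (roots of ā), the residue of Σ_W/(z·A(z)A(1/z)) at r_k is
Σ_W·r_k^{p−1}/(ā′(r_k)·B(r_k)), B(z) = 1 − Σ a_k z^k. A real pole
contributes one component (central frequency 0, or Nyquist for a negative
pole); a conjugate pair contributes one component with frequency
|arg r_k|/(2πT) and power twice the real part of one residue. The residues
of a stable model sum exactly to Σ_X (contour integral of the density), and
this conservation is tested against the independent Yule-Walker route at
1e-6 relative over 500 random stable models. Individual component powers
can be negative when poles interact; the values are retained (a warning is
emitted) because zeroing or clipping them would break conservation and
truncate replicate distributions. Poles closer than 1e-8 in the complex
plane violate the simple-pole assumption and raise an error.

Index conventions:

* LF band closed, [0.04, 0.15] Hz; HF half-open, (0.15, 0.4] Hz; components
  above 0.4 Hz count in neither band. f_LF is the LF-band component nearest
  0.1 Hz and is undefined (an explicit `None`, never a silent NaN) when the
  band is empty — the restriction to the LF band is what makes an
  underfitted order-3 model report "no LF component" rather than silently
  returning the HF peak.
* P_LFHF is the plain quotient of band power sums whenever both bands hold a
  component. Negative residue powers stay in the sums, so the extreme tails
  of a replicate distribution can contain negative ratios; clipping them
  would distort the percentile intervals the tests read.
* S_X = ½·ln(Σ_X/Σ_W) is nonnegative for any stable model and zero only for
  white noise.

## Resampling

**Monte Carlo.** M parameter sets are drawn from N(Â, Σ̂_A) (SVD-based
multivariate normal, so an exactly singular covariance — a zero-uncertainty
fixture — degenerates cleanly to the mean) and independently from
N(Σ̂_W, 2Σ̂_W²/N). Draws with Σ_W ≤ 0 or unstable coefficients are rejected
and redrawn — rejection preserves the support of valid AR models, and the
count is reported for diagnostics. If more than half of all draws are
invalid (attempt cap 20·M), the scheme refuses: the Gaussian approximation
is too distorted near the stability boundary to be trusted.

**Bootstrap.** Residuals are mean-centered (standard residual-bootstrap
practice) and resampled with replacement into V; the surrogate series is
X̃ = Z·Â + V on the **original fixed regressor matrix**, and Ã, Σ̃_W are
re-estimated by the same least-squares formulas on (Z, X̃). Rebuilding the
lag matrix from X̃ would discard p more samples for no inferential gain; a
`regenerate=True` flag provides the alternative recursive scheme for
comparison. Re-estimates that come out unstable keep their parameters but
have all indexes marked undefined.

Both engines map replicates to indexes through one vectorized kernel
(stacked companion-matrix eigenvalues, batched Yule-Walker solves, batched
residues); the scalar public operations call the same kernel with batch
size 1, so point estimates and replicates agree bitwise.

**Summaries and tests.** Confidence limits are the 5/25/50/75/95 percentiles
of the defined replicate values, linear-interpolation rule (fixed and
documented because the 5/95 points of M = 1000 samples are sensitive to the
rule). A summary built from fewer than 90% defined replicates is flagged
unreliable. The two-recording difference test permutes one replicate set
(seeded), differences element-wise (random pairing — all M×M combinations
would not be independent), drops undefined pairs (error below 10), and
rejects H0 iff zero is strictly outside the closed central percentile
interval; a boundary hit is conservatively not significant.

**Seeding.** One master integer seed; the MC draw stream, BS resample
stream, trend phase, per-run simulation seeds and test-pairing streams are
derived as named substreams (CRC-keyed `SeedSequence` spawns, stable across
processes). Same fit + same seed reproduces any replicate set bit for bit.

## Simulators

The benchmark is specified by poles, not coefficients: real VLF pole 0.65,
LF pair modulus 0.8 at 0.1 Hz, HF pair modulus 0.92 at 0.25 Hz, unit
innovation variance, T = 1 s, N = 300 — a 5-minute R-R recording at a 1 s
mean heart period. (The coefficient vector conventionally printed for this
configuration disagrees with its own pole specification in the lag-2 and
lag-4 entries; coefficients here are therefore always derived from the
poles, which reproduces the printed a₁ = 1.944, a₃ = 2.062, a₅ = 0.352.)
All simulators share one sample-by-sample recursion kernel and innovation
stream, so the nonlinear variants reduce bit-for-bit to the linear
simulator when their extra term is disabled. Burn-in is 1000 samples by
default — the 0.92-modulus pole needs several hundred samples for the
zero-state transient to decay.

* *Quadratic*: x(n) gains β(x²(n−1) − x²(n−2)). The term acts like ~2βx per
  unit lag difference and can destabilize the near-unit-root dynamics: at
  β = 0.06 most trajectories diverge. Divergence is monitored (|x| > 10⁶)
  and aborts with the seed in the message.
* *Threshold*: two regimes switched on x(n−1) vs γ, with γ expressed as a
  multiple of the *standard deviation* of the first regime's stationary
  process (the natural scale for an occupancy threshold). The second
  regime's default coefficients are the conventional printed values for a
  slower, weaker LF pair (ρ = 0.4 at 0.07 Hz); the printed vector is kept
  verbatim even though re-deriving it from those poles gives slightly
  different numbers.
* *Trend*: adds a sinusoid with amplitude expressed as a multiple of the
  input's sample SD and a seeded uniform phase (fixed phase available).

The gold standard generates many independent realizations of the true
process, fits each at the true (or an overridden) order, and collects the
index values — the sampling distribution the single-recording schemes try
to reproduce, available only in simulation.

What the generators deliberately do **not** emulate: physiologically
mechanistic heart-period generation (IPFM, respiratory coupling),
non-Gaussian innovations, ectopy/artefacts, or the manual editing applied
to real recordings. Passing the simulation studies therefore shows the
resampling machinery is calibrated for linear-Gaussian (and mildly
perturbed) dynamics, not that any recorded series satisfies those
assumptions.

## Study drivers and problem sizes

`run_simulation_study` runs `runs` independent realizations per grid
configuration (simulate → fit → resample → summarize) and difference-tests
per-run pairs between consecutive configurations. The gold-standard
percentiles per configuration are the percentiles of the per-run point
estimates — the same "many realizations of the original process"
construction, at zero extra cost. The default study size (100 runs,
M = 1000, N = 300) matches the validation design; the batched kernels put a
full three-configuration sweep at a few seconds on one CPU, so no test
needs to scale it down. Unit tests use 5–20 runs and M = 200–400 where only
the plumbing is under test.

`run_cohort_analysis` applies the same machinery per subject and task:
AIC order in [5, 15], fit, indexes, MC limits (MC is the default — BS gives
very similar limits at ~3× the cost; selectable), per-subject task-pair
tests, and a group summary per task pair and index: median and IQR of the
within-subject point-estimate differences, a Wilcoxon signed-rank p (scipy
routine — supporting output, not a contribution of this package), and the
percentage of subjects with an individually significant increase / no
change / decrease.

`binomial_false_positive_bound(n, p, conf)` gives the chance-compatible
ceiling on detection counts (9 for 100 trials at p = 0.05, 95% confidence).

## Known limitations

* All inference inherits the linear-stationary-Gaussian and correct-order
  assumptions; confidence limits cannot repair a misspecified model, and
  the order-mismatch study shows underfitting shifts S_X so far that every
  pair tests as different.
* Spectral and entropy indexes from AR fits are biased estimators; MC/BS
  intervals are centered on the *estimate*, the gold standard on the
  *truth*, so empirical coverage of a 90% interval is asserted in a wide
  80–98% band rather than at the nominal level.
* P_LFHF detection counts near the LF band edge (LF pole at 0.05 Hz) are
  sensitive to how the decomposition treats components drifting below
  0.04 Hz; replicate distributions there are heavy-tailed and ~15% of
  replicates lose the LF component entirely.
* The t-distribution of the regression coefficients is approximated as
  Gaussian, adequate for N > 100; behaviour for very short records (< 120
  beats) is untested and the bootstrap is the safer choice there.
* Analytical (delta-method) intervals, all-pairs difference distributions
  and bias-corrected bootstrap variants are out of scope.
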