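# arci — single-recording confidence limits for AR-derived HRV indexes

Descriptive indexes of heart-rate variability (HRV) — the LF spectral peak
frequency, the LF/HF power ratio, information storage — are routinely
estimated from a *single* 5-minute R-R interval recording, yet they are
random quantities: a different stretch of the same physiological state would
give different numbers. `arci` attaches confidence limits and significance
tests to such single-recording estimates, so that a change between two
recordings (two tasks, two visits, two patients) can be judged against the
estimation uncertainty of each recording rather than against cohort
variability.

It is aimed at researchers in biomedical signal processing and autonomic
physiology who analyse short stationary segments of beat-to-beat series, and
at anyone estimating nonlinear functions of autoregressive model parameters
from one realization.

## Model and indexes

A zero-mean stationary series is modelled as AR(p):

    x(n) = Σ_{k=1..p} a_k x(n−k) + w(n),        w ~ N(0, Σ_W)

identified by least squares: Â = (ZᵀZ)⁻¹ZᵀX, Σ̂_W = (N−p)⁻¹Σŵ², with
parameter covariances Σ̂_A = Σ̂_W(ZᵀZ)⁻¹ and Var(Σ̂_W) = 2Σ̂_W²/N. The AR
spectrum P(f) = Σ_W·T / |A(e^{j2πfT})|² is split by the pole-residue method
into oscillatory components, one per real pole or conjugate pair, whose
powers sum exactly to the process variance Σ_X. Three indexes follow:

* **f_LF** — central frequency (Hz) of the LF-band (0.04–0.15 Hz) component
  nearest 0.1 Hz (the Mayer-wave peak);
* **P_LFHF** — ratio of LF-band to HF-band (0.15–0.4 Hz) component powers;
* **S_X = ½ ln(Σ_X/Σ_W)** — information storage (nats): how much of the
  present beat is linearly predictable from the past.

These are nonlinear functions of the parameters, so their sampling
distributions are built numerically from one fit:

* **Monte Carlo (MC)**: draw M parameter sets from N(Â, Σ̂_A) ×
  N(Σ̂_W, 2Σ̂_W²/N), rejecting unstable/negative draws;
* **Bootstrap (BS)**: resample the model residuals with replacement,
  regenerate the series as X̃ = ZÂ + V, and re-estimate.

Confidence limits are percentiles (5/25/50/75/95) of the M replicate index
values. Two estimates S1, S2 differ significantly at level α iff zero lies
outside the [100·α/2, 100·(1−α/2)] percentile interval of the randomly
paired S2−S1 replicate differences.

The package also ships the validation apparatus: a pole-parameterized AR(5)
benchmark emulating short-term HRV (VLF pole 0.65; LF pair 0.8 @ 0.1 Hz; HF
pair 0.92 @ 0.25 Hz), nonlinear (quadratic, threshold-switching) and
nonstationary (sinusoidal trend) variants, the multiple-realizations gold
standard, grid-sweep study drivers with detection counts, and a cohort
driver (per-recording AIC order selection, individual tests, Wilcoxon group
summary).

## Worked example

```python
import arci

model  = arci.benchmark_model()                    # HRV-like AR(5), Σ_W = 1
series = arci.simulate_linear(model, n=300, seed=42)
fit    = arci.fit_ar(series, order=5)
point  = arci.compute_indexes(fit.model)

mc = arci.mc_replicates(fit, m=1000, seed=0)
for name in ("f_lf", "p_lfhf", "s_x"):
    s = arci.confidence_summary(mc.index_array(name), getattr(point, name))
    lo, hi = s.interval()
    print(f"{name:7s}{s.point_estimate:7.4f}  ({lo:.3f}, {hi:.3f})")
```

prints (seed 42; true values f_LF = 0.1, P_LFHF = 3.498, S_X = 1.025):

```
f_lf    0.0953  (0.079, 0.118)
p_lfhf  4.1133  (2.170, 6.273)
s_x     0.8998  (0.836, 0.994)
```

i.e. the single 300-beat recording pins the LF peak to ±0.02 Hz, while the
LF/HF ratio is only known to within roughly a factor of 3 — exactly the kind
of information a point estimate hides. The scripts in `examples/` walk
through fitting, MC-vs-BS limits, the two-recording difference test, a
simulation sweep with detection counts, and a synthetic cohort analysis;
each prints the numbers it computes and what they mean. A thin CLI mirrors
the library (`arci fit|indexes|ci|diff|simulate|study|cohort`, see
`arci --help`) for shell use on R-R text files.

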