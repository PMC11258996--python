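# Methods

This note documents the models, algorithms and parameter choices
behind `neotheta`, the assumptions they rest on, and what the
simulation-based tests do and do not establish about real infant EEG.

## Signal model and preprocessing

The recording model is a channels × samples matrix in μV at 500 Hz
with stimulus-onset markers.  The analysis band is 1–8 Hz (delta +
theta), isolated with a Chebyshev type II band-pass of design order 4
(8th-order band filter), 30 dB stopband attenuation, applied
forward–backward (`sosfiltfilt`) so the net phase shift is zero and
the effective attenuation doubles in dB.  The named filter family fixes
neither type, order nor edge placement; we place the stopband edges one
octave outside the passband (0.5 and 16 Hz), which keeps mid-band gain
within 0.1 % of unity (type II is monotone in the passband) while
giving ≥ 60 dB at one octave outside the band after the double pass.
Filtering always precedes epoching so filter transients never sit
inside epoch interiors.

Epochs span 2,560 ms — 400 ms pre-stimulus, 2,160 ms post-stimulus —
as half-open sample windows `[onset − pre, onset + post)`, with
`round(duration · fs)` samples (1,280 at 500 Hz).  Rejection stages run
in a fixed order and each epoch's status is set by the first stage that
fires, which makes the chain idempotent:

1. **Peak-to-peak**: max over channels of (max − min) strictly greater
   than 150 μV.
2. **SD ratio**: the epoch SD (pooled over channels × samples; a
   per-channel variant is available) strictly outside
   (mean SD / 3, 3 × mean SD) of the currently surviving epochs.
   Because the reference mean itself depends on which epochs survive,
   the rule is iterated to a fixed point starting from the stage-1
   survivors; a single-pass mode is available since the original
   convention is ambiguous.  The fixed point always exists: the
   survivor set shrinks monotonically.
3. **Manual mask**: an optional user-supplied boolean vector standing
   in for visual inspection, which is not automatable.

Participants need at least 20 surviving epochs in *each* condition
(inclusive bound) to enter the group analysis.

## Time-frequency decomposition

Complex Morlet wavelets with 3.5 cycles: Gaussian envelope of width
σ_t = 3.5/(2πf) (111.4 ms at 5 Hz) under a complex exponential,
evaluated at 1–8 Hz in 1 Hz steps.  The kernel is truncated at ±5σ_t:
±4σ_t leaves a plateau ripple of ~4·10⁻⁵ in the modulus, which shows
up as a spurious phase dependence of the amplitude; ±5σ_t brings it
below 10⁻⁷, and the truncation width is a parameter for anyone who
wants the narrower kernel.  Normalization is *unit amplitude*: the
kernel is scaled by 2/Σ(envelope) so a unit sinusoid at the centre
frequency yields plateau modulus 1.0, making maps read directly in μV
of spectral amplitude (the modulus, not power).  The published
description of the original toolbox does not fix its normalization, so
absolute amplitudes (and hence the absolute scale of the discrimination
measure) are comparable only up to a global factor; every statistical
result in the pipeline is invariant to that factor.

At 500 Hz the 1 Hz kernel spans ≈ 5.6 s — longer than the 2.56 s
epochs this design transforms at 1 Hz.  Kernels longer than the epoch
are symmetrically truncated to the epoch length and renormalised by the
lost envelope mass (a `strict=True` flag turns this into an error).
Convolution uses zero padding; the 200 ms trim removes edge distortion
well at ≥ 4 Hz (residual edge bias < 10 %) but not at 1–2 Hz, where the
kernel is much wider than the trim — a known limitation that affects
both conditions identically and therefore largely cancels in the paired
difference.

Per-epoch amplitude maps are averaged within condition, trimmed by
200 ms per side (time axis −200 … +1960 ms), and baseline-corrected per
frequency row by subtracting the row mean over [−200, 0) ms.  Baseline
correction is a one-shot state transition; applying it twice is an
error.

## Cluster-based permutation inference

Per channel, per-participant difference maps (native − unfamiliar)
enter a pixelwise paired t-test (df = n − 1; zero-variance pixels get a
sign-preserving sentinel rather than ±∞).  Pixels with |t| above the
two-tailed critical value (2.048 at df = 28) form 4-connected
components separately per sign; the cluster statistic is the **mass**
(sum of t over the component), which matches the magnitude of the
reported cluster-level statistic far better than a size statistic
would.  The null distribution is the maximum |mass| over both signs
under random per-participant sign flips — the exact null for a paired
design, since under exchangeability of the two conditions each
participant's difference map is symmetric in sign.  When 2ⁿ ≤ 2 ×
n_perm all sign patterns are enumerated; otherwise n_perm random
patterns are drawn and cluster p-values use the plus-one estimator
(b + 1)/(m + 1), so p is never 0.  Ties between a permuted and the
observed mass (the identity pattern always ties) are counted with a
small relative tolerance so the Monte-Carlo and exact routes agree.
Channels are analysed independently with no cross-channel correction,
mirroring the per-channel reporting convention of this literature; the
per-pixel effect size η²p = t²/(t² + df) is attached to every result.

The discrimination measure is the per-participant mean difference over
the most significant cluster's mask; a configured band × window mask
(e.g. 4–5 Hz × first half of the stimulus) is the fallback when no
cluster reaches significance, and can also be supplied explicitly for
replication against a published cluster region.

## Outcome models

"Path analysis" here means the set of separate OLS regressions whose
R/F/df structure matches the reported tables — not a joint SEM
covariance fit, which the printed per-equation F tests rule out.
Models 1–4 regress comp/prod at 12 and 18 months on the discrimination
measure; models 5–6 regress the 18-month scores on both 12-month
scores.  Each model uses its own listwise-complete subsample (attrition
differs by age), standardized betas b·sd(x)/sd(y), and two-tailed
tests.  Significance is judged at the Bonferroni-adjusted α = 0.05/2 =
0.025 (two comparisons per hypothesis).

Screening and diagnostics follow the operative rules: one-sided removal
of cases above mean + 3 SD of 12-month expressive vocabulary (the group
statistics include the candidate, so with small n a gross outlier can
mask itself — documented behaviour of the rule, and with a single
extreme the attainable z is capped at (n−1)/√n, below 3 until n = 12);
White and Breusch–Pagan heteroskedasticity tests as auxiliary
regressions of squared residuals (statistic n·R²; the
normality-assuming ESS/2 variant is behind a flag; note BP is blind to
variance symmetric in a centred predictor — that is White's x² term's
job); leverage (hat diagonal) with influential defined as strictly
above 2 × (k+1)/n; Cook's distance reported but not used for removal.
Influential cases found in the 18-month models are removed once and
those models refitted (3′/4′); refits never re-trigger removals.
Models 5′/6′ drop the predictors that did not survive the adjusted
alpha.  Pearson correlations (two-tailed) relate comprehension and
production within age.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not infant electrophysiology:

* **Background**: per-channel independent Gaussian 1/f noise
  (exponent 1, flat below 1 Hz), broadband RMS 3 μV.  The scale was
  chosen by a power analysis: the group-level t at burst pixels should
  be dominated by the configured between-participant gain SD, as the
  very large reported pixel effect sizes imply a small measurement
  contribution.  Real newborn EEG is larger and spatially correlated;
  neither matters for exercising the pipeline's rules.
* **Burst**: a Hann-ramped (10 % per edge) sinusoid at 5 Hz added to
  the native-language condition over 0–1080 ms post-onset (the first
  half of the stimulus).  Because the pipeline averages amplitude
  moduli across epochs, adding a coherent amplitude A to band noise
  raises the expected measured amplitude by less than A (Rician mean);
  the generator inverts the Rician mean equation (and the filter's
  passband gain) so the **expected measured increment equals the
  configured gain**.  Negative gains place the burst in the comparison
  condition, since amplitude cannot be driven below the background.
* **Gains**: Normal(0.204, 0.298) μV per participant by default — the
  generating counterparts of the observed discrimination summary.
* **Artifacts**: with probability 0.1 per epoch, a 300 ms in-band
  (3 Hz) transient of 200 μV on a random channel — in-band so the
  band-pass cannot remove it and the 150 μV rule must.
* **Vocabulary**: standardized latents z = βx + √(1−β²)ε from the
  standardized true gain x, with defaults β = 0.484 / 0.147 (12-month
  comprehension / production) and 0.408 / 0.303 (18-month direct).  The
  18-month latents combine x and the 12-month latent with weights
  solved so the direct *and* the cross-age correlations (0.724 / 0.656)
  hold simultaneously; the solved residual variance must be
  non-negative, which config validation enforces.  Latents map to CDI
  counts via round(max(0, μ + σz)) with μ₁₂ = 30, σ₁₂ = 15, μ₁₈ = 60,
  σ₁₈ = 20 (free parameters at the order of magnitude of the 83- and
  97-word checklists); growth holds in expectation, not per
  participant.  Attrition is missing-completely-at-random at rates
  22/29 (12 mo) and 27/29 (18 mo), since no attrition mechanism is
  documented.
* **Seeding**: one global seed expands counter-wise into
  per-participant, per-stream sub-seeds, so extending a cohort never
  reshuffles existing participants; identical (config, seed) gives
  byte-identical output.

## Calibration and recovery studies (sizes used)

* Null calibration of the cluster test: 500 cohorts of n = 12 at
  100 Hz (8 × 216 grid), 12 epochs/condition, n_perm = 200 — measured
  type-I error ≈ 0.05.  The sign-flip test is exact under the null, so
  this checks the implementation, not the theory.
* Regression null: 500 cohorts with β = 0, n = 22 — rejection at the
  adjusted α ≈ 0.025.
* Effect-size recovery: 200 cohorts at β = 0.484, n = 22 — mean
  estimated beta within 0.05 (the small downward attenuation comes from
  count rounding and the finite-sample bias of r).
* Burst detection: 20 cohorts of n = 29 at the full 500 Hz grid,
  n_perm = 1000, planted mean gain 0.5 μV — a significant positive
  cluster covering (5 Hz, first half) in ≥ 90 % of seeds (observed:
  all).

A deliberate limitation: at the *empirical* default gain
(mean 0.204, SD 0.298 — a standardized effect of d ≈ 0.69 whose own
cluster p was near the significance boundary), detection power is
about 70–80 %, not ≥ 90 %.  This is a property of the max-mass
permutation statistic at that effect size — the permutation null is
itself inflated by the planted effect under sign flips — and was
confirmed against an independent implementation
(`mne.stats.permutation_cluster_1samp_test`, which reproduces our
cluster p-values to ±0.002).  The detection-validation study therefore
uses the clearly detectable 0.5 μV burst, and the acceptance script
reports the rate at both gains so the power ceiling at the empirical
effect size stays visible.

## Numerical conventions

Half-open windows everywhere (`[start, end)` in ms); strict
inequalities at every rejection/influence bound, so values exactly at
a threshold survive; time axes in ms relative to stimulus onset;
amplitudes in μV.  Degenerate inputs have defined behaviour: zero
variance in a t-test pixel → sentinel with warning; constant residuals
→ heteroskedasticity statistic (0, 1); leverage 1 → Cook's distance
NaN with warning; model p-values floored at 10⁻³⁰⁰ rather than 0.

## What the tests do not show

Passing on synthetic cohorts demonstrates correctness of the rules and
calibration of the inference under the generator's assumptions —
independent pink noise, a single oscillatory burst, linear
gain–vocabulary coupling, MCAR attrition.  Real newborn data add
volume-conducted spatial correlation, non-stationary sleep-stage
dynamics, artifact families with structure the SD rule may miss, and
attrition that is unlikely to be completely at random; none of these
are modelled, and conclusions about real cohorts must rest on the real
data, not on these tests.
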