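# neotheta

Newborns can discriminate their native language from a rhythmically
different unfamiliar one, and the size of that neural discrimination at
birth may carry information about the language development that
follows.  `neotheta` is a tested analysis pipeline for that question:
it takes multichannel newborn EEG recorded while sentences in two
languages are played (10 channels of the 10–20 system, 500 Hz), builds
theta-band spectral-amplitude maps per condition, tests the
condition difference with cluster-based permutation statistics, derives
a per-participant **discrimination measure**, and relates it to
receptive and expressive vocabulary (CDI word counts) at 12 and
18 months with standardized-beta path models and full residual /
influence diagnostics.

It is aimed at developmental-EEG researchers who want a transparent,
reproducible implementation of this analysis chain — and it ships a
first-class synthetic-data generator so every stage is testable without
any infant data.

## The analysis in brief

1. **Preprocess** — zero phase-shift Chebyshev band-pass (1–8 Hz),
   segmentation into 2,560 ms epochs (400 ms pre-stimulus), then a
   three-stage rejection: peak-to-peak > 150 μV; epoch SD outside
   (mean SD / 3, 3 × mean SD) of the surviving epochs (iterated to a
   fixed point); an optional manual mask.  Participants with fewer than
   20 surviving epochs in either condition are excluded.
2. **Time-frequency** — complex Morlet wavelets, 3.5 cycles
   (σ_t = 3.5/(2πf)), 1–8 Hz in 1 Hz steps; the modulus gives spectral
   *amplitude* in μV (not power; a unit sinusoid reads 1.0).  Per-epoch
   maps are averaged, 200 ms trimmed at each end (leaving −200 … +1960
   ms), and each frequency row is baseline-corrected by its mean over
   the 200 ms pre-stimulus window.
3. **Cluster statistics** — pixelwise paired t maps across
   participants; 4-connected clusters above the two-tailed critical t
   (t(28) = 2.048 for n = 29); cluster **mass** (sum of t) referred to
   the permutation distribution of the maximum |mass| under random
   per-participant sign flips (exact enumeration when 2ⁿ is small,
   plus-one Monte-Carlo p otherwise).  The discrimination measure is
   each participant's mean amplitude difference (native − unfamiliar)
   over the significant cluster.
4. **Outcome models** — OLS path models on the per-model
   listwise-complete samples: discrimination → comp/prod at 12 and 18
   months (models 1–4) and 12-month → 18-month vocabulary (models 5–6),
   judged at the Bonferroni-adjusted α = 0.025; White and Breusch–Pagan
   heteroskedasticity tests; leverage > 2 × average flags influential
   cases, whose removal yields the post-hoc models 3′/4′; 5′/6′ drop
   non-surviving predictors.

The synthetic generator produces 1/f background EEG, a Hann-ramped
theta burst in the native condition over the first half of the
stimulus with per-participant gain heterogeneity (Rician-mean
calibrated, so the configured gain *is* the expected measured amplitude
increment), injected artifacts the 150 μV rule must catch, and
vocabulary counts linearly coupled to the true gain with configurable
standardized effect sizes and longitudinal attrition.

## Worked example

Run the full pipeline on a simulated 29-infant cohort with a clearly
detectable burst (mean gain 0.5 μV at 5 Hz, channel F4):

```python
from neotheta import synth
from neotheta.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(sim=synth.SimConfig(channels=("F4",), mean_gain=0.5),
                     seed=3)
result = run_pipeline(cfg, out_dir="demo_run")
```

This prints (via the manifest / report objects):

```
n_included: 29
top cluster: sign +1 mass 13935.8 p 0.0010, 4-8 Hz, 26-1086 ms
discrimination mean 0.272 sd 0.213 range (-0.120, 0.693)
model dependent     R  r_square      F     p         beta  n
    1    comp12 0.472     0.223  6.016 0.023        0.472 23
    2    prod12 0.436     0.190  4.919 0.038        0.436 23
    3    comp18 0.500     0.250  8.354 0.008        0.500 27
    4    prod18 0.507     0.258  8.671 0.007        0.507 27
    5    comp18 0.749     0.561 12.122 0.000 0.628; 0.203 22
    6    prod18 0.721     0.519 10.257 0.001 0.128; 0.649 22
   3'    comp18 0.362     0.131  3.463 0.076        0.362 25
   4'    prod18 0.391     0.153  4.158 0.053        0.391 25
   5'    comp18 0.728     0.529 22.500 0.000        0.728 22
   6'    prod18 0.712     0.507 20.548 0.000        0.712 22
```

Reading it: all 29 simulated infants survive epoch rejection; the
permutation test finds one significant positive cluster containing the
planted (5 Hz, first-half) burst region (mass 13936, p = 0.001); the
per-participant discrimination measures average 0.27 μV; and the
discrimination at "birth" predicts comprehension at 12 months with a
standardized beta of 0.47 at the adjusted α = 0.025 (p = 0.023, n = 23
after attrition), while the 12→18-month vocabulary paths carry betas
near 0.7.  In a univariate model |beta| equals R, and F = t² — these
identities are asserted in the test suite.

The same pipeline is available from a shell:

```bash
neotheta pipeline --seed 3 --out demo_run      # synth → … → predict
neotheta simulate --seed 1 --out sim/          # recordings + vocabulary
neotheta predict --table measures.csv --out report/
```

Recordings can also be read from BrainVision (`.vhdr`) or EDF files;
simulated data are written to a documented HDF5 container.

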