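"""Synthetic newborn-EEG cohorts with linked vocabulary outcomes.

The generator emulates the statistical structure the downstream
analysis assumes, so every stage is testable without any recorded data:

* 1/f (pink) Gaussian background noise per channel;
* a theta-band (default 5 Hz) oscillatory burst added to the native-
  language condition during the first half of the post-stimulus window,
  with per-participant amplitude heterogeneity (the "gain");
* occasional high-amplitude in-band artifacts that the 150 μV
  peak-to-peak rule should catch;
* vocabulary scores at 12 and 18 months linearly coupled to the true
  per-participant gain with configurable standardized effect sizes,
  mapped to CDI-scale word counts with missing-completely-at-random
  longitudinal attrition.

Because the pipeline measures *spectral amplitude* (the modulus of the
wavelet coefficient) averaged across epochs, adding a coherent sinusoid
of amplitude A to band-limited noise raises the expected amplitude by
less than A (the Rician-mean effect).  The generator therefore
calibrates the injected burst amplitude by inverting the Rician mean so
that the *expected measured increment* equals the configured gain; see
``calibrated_burst_amplitude``.  Negative gains place the burst in the
comparison condition instead, since amplitude cannot drop below the
background by adding a signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CANONICAL_CHANNELS, EEGRecording
from .preprocess import design_bandpass, filtfilt_gain
from .tfr import morlet_kernel

logger = logging.getLogger(__name__)

# Sub-seed streams: participant i, stream s -> SeedSequence(seed, (i, s)).
# Counter-based, so a cohort can be extended without reshuffling the
# randomness of existing participants.
_STREAM_GAIN = 0
_STREAM_EEG = 1
_STREAM_VOCAB = 2


def participant_rng(seed, participant, stream):
    """Deterministic per-participant, per-stream random generator."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(int(participant),
                                                     int(stream))))


@dataclass
class SimConfig:
    """Generating conditions for a synthetic cohort.

    Defaults follow the study design this emulates: 500 Hz sampling,
    2,560 ms epochs (400 ms pre-stimulus), ~40/35 usable epochs per
    condition, a 5 Hz burst over the first half of the 2,160 ms
    stimulus, per-participant gains of mean 0.204 and SD 0.298 μV, and
    standardized vocabulary effect sizes 0.484/0.147 (12 mo), 0.408/0.303
    (18 mo direct) and 0.724/0.656 (12→18 mo).
    """

    n_participants: int = 29
    fs: float = 500.0
    n_epochs_a: int = 40
    n_epochs_b: int = 35
    epoch_pre_ms: float = 400.0
    epoch_post_ms: float = 2160.0
    noise_exponent: float = 1.0
    noise_rms: float = 3.0              # broadband background RMS, μV
    theta_freq: float = 5.0
    burst_window: tuple = (0.0, 1080.0)  # ms, within post-stimulus
    ramp_fraction: float = 0.1           # Hann ramp span per burst edge
    mean_gain: float = 0.204             # μV, expected amplitude increment
    sd_gain: float = 0.298
    gain_fraction_b: float = 0.0         # optional residual burst in B
    artifact_rate: float = 0.1           # per-epoch probability
    artifact_amp: float = 200.0          # μV (> the 150 μV rejection bound)
    artifact_freq: float = 3.0           # Hz, in-band so filtering keeps it
    artifact_dur_ms: float = 300.0
    isi_range_ms: tuple = (1000.0, 1500.0)
    beta_comp12: float = 0.484
    beta_prod12: float = 0.147
    beta_comp18: float = 0.408
    beta_prod18: float = 0.303
    beta_comp12_18: float = 0.724
    beta_prod12_18: float = 0.656
    vocab_mu12: float = 30.0
    vocab_sd12: float = 15.0
    vocab_mu18: float = 60.0
    vocab_sd18: float = 20.0
    p_obs_12: float = 22.0 / 29.0        # longitudinal attrition (MCAR)
    p_obs_18: float = 27.0 / 29.0
    channels: tuple = CANONICAL_CHANNELS
    burst_channels: tuple = ("F4",)
    condition_a: str = "french"
    condition_b: str = "english"
    filter_low: float = 1.0
    filter_high: float = 8.0
    calibrate_burst: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fs <= 2 * self.theta_freq:
            raise ValueError("fs must exceed twice the burst frequency")
        for p in (self.artifact_rate, self.p_obs_12, self.p_obs_18):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        w0, w1 = self.burst_window
        if not (0.0 <= w0 < w1 <= self.epoch_post_ms):
            raise ValueError("burst_window must lie within the post-stimulus "
                             "interval")
        for name in ("beta_comp12", "beta_prod12", "beta_comp18",
                     "beta_prod18", "beta_comp12_18", "beta_prod12_18"):
            b = getattr(self, name)
            if not -1.0 < b < 1.0:
                raise ValueError(f"{name}={b} outside (-1, 1)")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if self.sd_gain < 0 or self.noise_rms < 0:
            raise ValueError("scales must be non-negative")
        for ch in self.burst_channels:
            if ch not in self.channels:
                raise ValueError(f"burst channel {ch!r} not in channels")
        # cross-age weights must leave non-negative residual variance
        _cross_age_weights(self.beta_comp18, self.beta_comp12_18,
                           self.beta_comp12)
        _cross_age_weights(self.beta_prod18, self.beta_prod12_18,
                           self.beta_prod12)

    def to_dict(self):
        d = asdict(self)
        for key in ("burst_window", "isi_range_ms", "channels",
                    "burst_channels"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("burst_window", "isi_range_ms", "channels",
                    "burst_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent per-participant state of a simulated cohort."""

    participant_ids: list
    gains: np.ndarray     # true theta amplitude increments, μV
    latent: np.ndarray    # standardized gains driving vocabulary
    seed: int

    def __post_init__(self):
        self.gains = np.asarray(self.gains, dtype=float)
        self.latent = np.asarray(self.latent, dtype=float)
        if not (len(self.participant_ids) == len(self.gains)
                == len(self.latent)):
            raise ValueError("ground-truth arrays must align")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"participant_ids": list(self.participant_ids),
                       "gains": self.gains.tolist(),
                       "latent": self.latent.tolist(),
                       "seed": self.seed}, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["participant_ids"], d["gains"], d["latent"], d["seed"])


def make_pink_noise(n_samples, fs, exponent=1.0, seed=None, rms=1.0):
    """Zero-mean noise with power spectral density ∝ 1/f^exponent.

    Synthesized in the frequency domain: independent complex Gaussian
    spectral coefficients shaped by f^(−exponent/2) above 1 Hz (flat
    below, to keep finite power), inverted, and scaled to the requested
    RMS.  ``exponent=0`` is the white-noise limit.  Deterministic for a
    fixed seed; ``seed`` may also be a ``numpy.random.Generator``.
    """
    n_samples = int(n_samples)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _cross_age_weights(beta_direct, beta_cross, beta_12):
    """Weights (a, b, c) so z18 = a·x + b·z12 + c·ε has the requested
    correlations with the gain latent x (``beta_direct``) and the
    12-month latent z12 (``beta_cross``), given corr(x, z12)=beta_12."""
    denom = 1.0 - beta_12 ** 2
    b = (beta_cross - beta_direct * beta_12) / denom
    a = beta_direct - b * beta_12
    c2 = 1.0 - (a * a + b * b + 2.0 * a * b * beta_12)
    if c2 < 0:
        raise ValueError(
            f"inconsistent effect sizes: direct={beta_direct}, "
            f"cross={beta_cross}, 12mo={beta_12} imply negative residual "
            "variance")
    return a, b, float(np.sqrt(c2))


def estimate_band_sigma(cfg: SimConfig, duration_s=60.0, seed=12345):
    """Per-component std of the wavelet coefficient of filtered background.

    Simulates ``duration_s`` of pink noise, applies the analysis
    band-pass, convolves with the Morlet kernel at ``theta_freq`` and
    returns the standard deviation of the coefficient's real part over
    the interior — the Rician σ used for burst calibration.
    """
    from scipy.signal import fftconvolve, sosfiltfilt

    if cfg.noise_rms == 0:
        return 0.0
    n = int(duration_s * cfg.fs)
    x = make_pink_noise(n, cfg.fs, cfg.noise_exponent, seed=seed,
                        rms=cfg.noise_rms)
    sos = design_bandpass(cfg.fs, cfg.filter_low, cfg.filter_high)
    x = sosfiltfilt(sos, x)
    kern = morlet_kernel(cfg.theta_freq, cfg.fs)
    coef = fftconvolve(x, kern, mode="same")
    edge = int(2.0 * cfg.fs)
    return float(np.std(coef.real[edge:-edge]))


def calibrated_burst_amplitude(target, sigma_c):
    """Sinusoid amplitude whose expected amplitude increment is ``target``.

    The measured per-epoch amplitude of (burst + band noise) follows a
    Rice distribution with location A and scale σ_c; its mean exceeds
    the noise-only (Rayleigh) mean by less than A.  Solving
    ``E|A + n| − E|n| = target`` for A undoes that shrinkage.  With no
    background (σ_c = 0) the answer is simply the target.
    """
    if target <= 0:
        return 0.0
    if sigma_c <= 0:
        return float(target)
    base = sigma_c * np.sqrt(np.pi / 2.0)

    def gap(a):
        return stats.rice.mean(a / sigma_c, scale=sigma_c) - base - target

    hi = target + 10.0 * sigma_c
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-6))


def _burst_waveform(n_samples, fs, freq, amplitude, phase, ramp_fraction):
    """Hann-ramped sinusoidal burst (ramps span ``ramp_fraction`` per edge)."""
    t = np.arange(n_samples) / fs
    wave = amplitude * np.cos(2.0 * np.pi * freq * t + phase)
    n_ramp = int(round(ramp_fraction * n_samples))
    env = np.ones(n_samples)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return wave * env


def draw_ground_truth(cfg: SimConfig, seed) -> GroundTruth:
    """Per-participant true gains and the standardized latent behind them."""
    ids = [f"P{i:02d}" for i in range(cfg.n_participants)]
    gains = np.empty(cfg.n_participants)
    for i in range(cfg.n_participants):
        rng = participant_rng(seed, i, _STREAM_GAIN)
        gains[i] = cfg.mean_gain + cfg.sd_gain * rng.standard_normal()
    if cfg.sd_gain > 0:
        latent = (gains - cfg.mean_gain) / cfg.sd_gain
    else:
        latent = np.zeros_like(gains)
    return GroundTruth(ids, gains, latent, int(seed))


def simulate_participant(cfg: SimConfig, participant_gain, seed,
                         sigma_c=None):
    """Continuous two-condition recording for one participant.

    The native condition (A) carries the theta burst when the gain is
    positive; a negative gain puts the burst in condition B.  Artifacts
    are injected per epoch with probability ``artifact_rate`` as
    high-amplitude in-band transients.  Returns ``(recording, info)``
    where ``info`` records the event table, artifact epochs and the
    calibrated burst amplitude actually injected.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``;
    ``sigma_c`` (background Rician σ at the burst frequency) may be
    passed in to avoid re-estimating it per participant.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n_pre = int(round(cfg.epoch_pre_ms / 1000.0 * fs))
    n_post = int(round(cfg.epoch_post_ms / 1000.0 * fs))
    span = n_pre + n_post

    # block design: all condition-A epochs, then all condition-B epochs
    labels = ([cfg.condition_a] * cfg.n_epochs_a
              + [cfg.condition_b] * cfg.n_epochs_b)
    onsets = []
    cursor = n_pre + int(fs)  # 1 s lead-in
    for _ in labels:
        onsets.append(cursor)
        isi = rng.uniform(*cfg.isi_range_ms) / 1000.0
        cursor += span + int(round(isi * fs))
    n_samples = cursor + n_post + int(fs)

    data = np.empty((len(cfg.channels), n_samples))
    for c in range(len(cfg.channels)):
        data[c] = make_pink_noise(n_samples, fs, cfg.noise_exponent,
                                  seed=rng, rms=cfg.noise_rms)

    gain = float(participant_gain)
    target_a = max(gain, 0.0)
    target_b = max(-gain, 0.0) + cfg.gain_fraction_b * target_a
    if cfg.calibrate_burst:
        if sigma_c is None:
            sigma_c = estimate_band_sigma(cfg)
        g_filt = filtfilt_gain(fs, cfg.theta_freq, cfg.filter_low,
                               cfg.filter_high)
        amp_a = calibrated_burst_amplitude(target_a, sigma_c) / g_filt
        amp_b = calibrated_burst_amplitude(target_b, sigma_c) / g_filt
    else:
        amp_a, amp_b = target_a, target_b

    w0 = int(round(cfg.burst_window[0] / 1000.0 * fs))
    w1 = int(round(cfg.burst_window[1] / 1000.0 * fs))
    burst_len = w1 - w0
    burst_rows = [cfg.channels.index(ch) for ch in cfg.burst_channels]

    artifact_epochs = []
    art_len = int(round(cfg.artifact_dur_ms / 1000.0 * fs))
    events = []
    for k, (onset, label) in enumerate(zip(onsets, labels)):
        events.append((onset, label))
        amp = amp_a if label == cfg.condition_a else amp_b
        if amp > 0 and burst_len > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = _burst_waveform(burst_len, fs, cfg.theta_freq, amp,
                                   phase, cfg.ramp_fraction)
            for row in burst_rows:
                data[row, onset + w0:onset + w1] += wave
        if rng.uniform() < cfg.artifact_rate:
            artifact_epochs.append(k)
            row = rng.integers(0, len(cfg.channels))
            start = onset - n_pre + int(rng.integers(0, max(span - art_len,
                                                            1)))
            pulse = _burst_waveform(art_len, fs, cfg.artifact_freq,
                                    cfg.artifact_amp, 0.0, 0.25)
            data[row, start:start + art_len] += pulse

    rec = EEGRecording(data, fs, list(cfg.channels), events)
    info = {"events": events, "artifact_epochs": artifact_epochs,
            "burst_amplitude_a": amp_a, "burst_amplitude_b": amp_b,
            "gain": gain, "sigma_c": sigma_c}
    return rec, info


def iter_recordings(cfg: SimConfig, truth: GroundTruth, sigma_c=None):
    """Yield ``(participant_id, recording, info)`` for a whole cohort.

    The background Rician σ is estimated once and shared, so cohort
    simulation stays linear in the number of participants.
    """
    if sigma_c is None and cfg.calibrate_burst:
        sigma_c = estimate_band_sigma(cfg)
    for i, pid in enumerate(truth.participant_ids):
        ss = np.random.SeedSequence(truth.seed, spawn_key=(i, _STREAM_EEG))
        rec, info = simulate_participant(cfg, truth.gains[i], ss,
                                         sigma_c=sigma_c)
        yield pid, rec, info


def simulate_vocabulary(truth: GroundTruth, cfg: SimConfig,
                        seed=None) -> pd.DataFrame:
    """Vocabulary table linearly coupled to the true gains.

    Standardized latent scores follow ``z = β·x + √(1−β²)·ε`` at 12
    months; the 18-month latents combine the gain latent and the
    12-month latent so both the direct (birth→18 mo) and cross-age
    (12→18 mo) standardized effects match the configuration.  Latents
    are mapped to plausible CDI word counts via
    ``round(max(0, μ_age + σ_age·z))`` and thinned by MCAR attrition.
    """
    n = len(truth.participant_ids)
    if n < 3:
        raise ValueError("need at least 3 participants")
    seed = truth.seed if seed is None else seed
    x = truth.latent
    ac, bc, cc = _cross_age_weights(cfg.beta_comp18, cfg.beta_comp12_18,
                                    cfg.beta_comp12)
    ap, bp, cp = _cross_age_weights(cfg.beta_prod18, cfg.beta_prod12_18,
                                    cfg.beta_prod12)

    rows = []
    for i, pid in enumerate(truth.participant_ids):
        rng = participant_rng(seed, i, _STREAM_VOCAB)
        e = rng.standard_normal(4)
        zc12 = cfg.beta_comp12 * x[i] + np.sqrt(1 - cfg.beta_comp12 ** 2) * e[0]
        zp12 = cfg.beta_prod12 * x[i] + np.sqrt(1 - cfg.beta_prod12 ** 2) * e[1]
        zc18 = ac * x[i] + bc * zc12 + cc * e[2]
        zp18 = ap * x[i] + bp * zp12 + cp * e[3]
        counts = {
            "comp12": round(max(0.0, cfg.vocab_mu12 + cfg.vocab_sd12 * zc12)),
            "prod12": round(max(0.0, cfg.vocab_mu12 + cfg.vocab_sd12 * zp12)),
            "comp18": round(max(0.0, cfg.vocab_mu18 + cfg.vocab_sd18 * zc18)),
            "prod18": round(max(0.0, cfg.vocab_mu18 + cfg.vocab_sd18 * zp18)),
        }
        if rng.uniform() >= cfg.p_obs_12:
            counts["comp12"] = counts["prod12"] = np.nan
        if rng.uniform() >= cfg.p_obs_18:
            counts["comp18"] = counts["prod18"] = np.nan
        rows.append({"participant_id": pid, **counts})
    return pd.DataFrame(rows)


def simulate_outcome_table(cfg: SimConfig, seed) -> pd.DataFrame:
    """Vocabulary table joined with the *true* gain as the predictor.

    A shortcut for effect-size recovery studies that do not need the
    EEG stage: ``discrimination_0m`` holds the true per-participant
    gain rather than a pipeline-measured value.
    """
    truth = draw_ground_truth(cfg, seed)
    tbl = simulate_vocabulary(truth, cfg)
    tbl.insert(1, "discrimination_0m", truth.gains)
    return tbl
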