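"""Morlet-wavelet time-frequency decomposition of epoched EEG.

The transform convolves each epoch with complex Morlet wavelets (3.5
cycles) at 1 Hz steps in the 1–8 Hz range and takes the modulus of the
complex coefficients, yielding spectral *amplitude* in μV — not power.
Per-epoch maps are averaged, the first and last 200 ms of the average
are trimmed to drop wavelet edge distortion, and each frequency row is
baseline-corrected by subtracting its mean over the 200 ms pre-stimulus
window.

Normalization is unit-amplitude: convolving a unit-amplitude sinusoid
at the wavelet's centre frequency yields a plateau modulus of 1, so
amplitude maps read directly in μV.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import CORRECTED, RAW, EpochSet, TFRMap

logger = logging.getLogger(__name__)

DEFAULT_FREQS = tuple(float(f) for f in range(1, 9))


def morlet_sigma_t(f, n_cycles=3.5):
    """Temporal width σ_t = n_cycles / (2π f) of the Gaussian envelope, s."""
    return n_cycles / (2.0 * np.pi * f)


def morlet_kernel(f, fs, n_cycles=3.5, trunc_sigmas=5.0):
    """Complex Morlet kernel at centre frequency ``f``.

    The kernel is a complex exponential under a Gaussian envelope with
    σ_t = n_cycles/(2πf), truncated at ±``trunc_sigmas``·σ_t, and
    scaled so that the convolution of a unit-amplitude sinusoid at
    ``f`` has plateau modulus 1.  Real and imaginary parts are cos/sin
    quadrature pairs sharing the same envelope.  The default ±5σ
    support keeps the truncation ripple of the plateau modulus below
    1e-6 (±4σ leaves ripple near 4e-5, visible as spurious phase
    dependence of the amplitude).
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f >= fs / 2:
        raise ValueError(f"frequency {f} Hz at or above Nyquist ({fs / 2} Hz)")
    sigma = morlet_sigma_t(f, n_cycles)
    half = int(np.ceil(trunc_sigmas * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-t ** 2 / (2.0 * sigma ** 2))
    kernel = envelope * np.exp(2j * np.pi * f * t)
    # Unit-amplitude normalization: a unit sinusoid contributes
    # (1/2)·Σ envelope to the modulus at the plateau.
    kernel *= 2.0 / envelope.sum()
    return kernel


def _fit_kernel(kernel, n_samples, strict):
    """Truncate a kernel symmetrically so it fits an epoch, renormalising.

    At 500 Hz the 1 Hz kernel (±4σ_t ≈ ±2.23 s) is longer than a 2.56 s
    epoch; rather than refuse the transform, the kernel is clipped to
    the epoch length and rescaled by the lost envelope mass so the
    unit-amplitude contract still holds for long stationary input.
    """
    if len(kernel) <= n_samples:
        return kernel
    if strict:
        raise ValueError(f"epoch ({n_samples} samples) shorter than kernel "
                         f"({len(kernel)} samples)")
    keep = n_samples if n_samples % 2 == 1 else n_samples - 1
    if keep < 3:
        raise ValueError("epoch far too short for this wavelet")
    half = (len(kernel) - keep) // 2
    clipped = kernel[half:half + keep]
    full = np.abs(kernel).sum()
    part = np.abs(clipped).sum()
    return clipped * (full / part)


def transform_epoch(signal, fs, freqs=DEFAULT_FREQS, n_cycles=3.5,
                    strict=False):
    """Wavelet-amplitude map(s) of one epoch or a batch of epochs.

    Parameters
    ----------
    signal : ndarray, (n_samples,) or (n_epochs, n_samples)
        Epoch signal(s) in μV.
    strict : bool
        If True, raise when any kernel is longer than the epoch instead
        of truncating it (see :func:`_fit_kernel`).

    Returns
    -------
    ndarray
        Amplitudes ≥ 0 with shape (n_freqs, n_samples) for a single
        epoch or (n_epochs, n_freqs, n_samples) for a batch.
    """
    sig = np.asarray(signal, dtype=float)
    single = sig.ndim == 1
    sig = np.atleast_2d(sig)
    n_ep, n_samp = sig.shape
    out = np.empty((n_ep, len(freqs), n_samp))
    for i, f in enumerate(freqs):
        kern = _fit_kernel(morlet_kernel(f, fs, n_cycles), n_samp, strict)
        conv = sps.fftconvolve(sig, kern[None, :], mode="same", axes=1)
        out[:, i, :] = np.abs(conv)
    return out[0] if single else out


def average_and_trim(maps, fs, t0_offset_ms=400.0, trim_ms=200.0,
                     freqs=DEFAULT_FREQS, channel=None, condition=None,
                     participant_id=None) -> TFRMap:
    """Average per-epoch maps and trim wavelet edge distortion.

    ``maps`` is (n_kept, n_freqs, n_times).  The element-wise mean is
    computed and ``trim_ms`` is removed at each end, so 2,560 ms epochs
    trimmed by 200 ms leave 2,160 ms maps spanning −200..+1960 ms
    around stimulus onset.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] == 0:
        raise ValueError("need at least one kept epoch to average")
    mean = maps.mean(axis=0)
    n_trim = int(round(trim_ms / 1000.0 * fs))
    times = np.arange(mean.shape[1]) / fs * 1000.0 - t0_offset_ms
    if n_trim > 0:
        if 2 * n_trim >= mean.shape[1]:
            raise ValueError("trim window longer than the epoch")
        mean = mean[:, n_trim:mean.shape[1] - n_trim]
        times = times[n_trim:len(times) - n_trim]
    return TFRMap(mean, np.asarray(freqs, dtype=float), times, RAW,
                  channel, condition, participant_id)


def baseline_correct(tfr: TFRMap, window=(-200.0, 0.0)) -> TFRMap:
    """Subtract each frequency row's mean over the pre-stimulus window.

    The correction is per frequency and uses the half-open window
    ``[start, end)`` in ms.  Applying it twice is a state error.
    """
    if tfr.baseline_state == CORRECTED:
        raise ValueError("map already baseline-corrected")
    lo, hi = window
    sel = (tfr.times >= lo) & (tfr.times < hi)
    if not sel.any():
        raise ValueError(f"baseline window {window} outside time axis "
                         f"[{tfr.times[0]}, {tfr.times[-1]}]")
    out = tfr.copy()
    out.amplitude = out.amplitude - out.amplitude[:, sel].mean(axis=1,
                                                               keepdims=True)
    out.baseline_state = CORRECTED
    return out


def epochs_to_tfr(eps: EpochSet, channel, condition, freqs=DEFAULT_FREQS,
                  n_cycles=3.5, trim_ms=200.0, baseline=(-200.0, 0.0),
                  participant_id=None) -> TFRMap:
    """Kept epochs of one condition/channel → averaged (corrected) TFR map."""
    ci = eps.channel_index(channel)
    kept = eps.kept_mask(condition)
    if not kept.any():
        raise ValueError(f"no kept epochs for condition {condition!r}")
    maps = transform_epoch(eps.data[kept, ci, :], eps.fs, freqs, n_cycles)
    tfr = average_and_trim(maps, eps.fs, t0_offset_ms=eps.t0_offset_ms,
                           trim_ms=trim_ms, freqs=freqs, channel=channel,
                           condition=condition, participant_id=participant_id)
    if baseline is not None:
        tfr = baseline_correct(tfr, baseline)
    return tfr
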