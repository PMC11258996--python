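"""Continuous-signal filtering, epoching, and epoch rejection.

The rejection chain has three ordered stages — peak-to-peak amplitude,
standard-deviation ratio, and an optional manual mask standing in for
visual inspection — followed by a per-participant inclusion rule based
on the number of surviving epochs per condition.  Stages set an epoch's
status at most once: the first stage that rejects an epoch wins, so
re-running the chain on its own output is a no-op.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import (EEGRecording, EpochSet, KEPT, REJECTED_MANUAL,
                         REJECTED_P2P, REJECTED_SD)

logger = logging.getLogger(__name__)


def design_bandpass(fs, low=1.0, high=8.0, order=4, stop_atten_db=30.0,
                    stop_factor=2.0):
    """Design the zero-phase Chebyshev band-pass (second-order sections).

    A Chebyshev type II design of the given order is placed with its
    stopband edges one octave (``stop_factor`` = 2) outside the passband,
    so that after the forward-backward application the attenuation one
    octave outside the band is at least 2 × ``stop_atten_db`` while the
    passband stays maximally flat (type II has no passband ripple).
    """
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist) "
                         f"for fs={fs}")
    f_lo = low / stop_factor
    f_hi = high * stop_factor
    if f_hi >= fs / 2:
        f_hi = 0.99 * fs / 2
        logger.warning("upper stopband edge clipped to %.2f Hz", f_hi)
    return sps.cheby2(order, stop_atten_db, [f_lo, f_hi], btype="bandpass",
                      output="sos", fs=fs)


def bandpass_filter(rec: EEGRecording, low=1.0, high=8.0, order=4,
                    stop_atten_db=30.0) -> EEGRecording:
    """Zero phase-shift band-pass filter of a continuous recording.

    Applied forward-backward (``sosfiltfilt``) so the net phase shift is
    zero and the effective magnitude response is the squared design
    response.  Filtering always happens on the continuous signal, never
    per epoch, to keep filter transients away from epoch interiors.
    """
    sos = design_bandpass(rec.fs, low, high, order, stop_atten_db)
    filtered = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return EEGRecording(filtered, rec.fs, list(rec.channel_names),
                        [tuple(e) for e in rec.events])


def filtfilt_gain(fs, freq, low=1.0, high=8.0, order=4, stop_atten_db=30.0):
    """Magnitude gain of the zero-phase filter at ``freq`` Hz (|H|²)."""
    sos = design_bandpass(fs, low, high, order, stop_atten_db)
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq / fs])
    return float(np.abs(h[0]) ** 2)


def segment_epochs(rec: EEGRecording, pre_ms=400.0, post_ms=2160.0) -> EpochSet:
    """Cut fixed-length epochs around each event onset.

    Each epoch spans ``round((pre_ms + post_ms)/1000 * fs)`` samples in
    the half-open window ``[onset - pre, onset + post)``; events too
    close to either recording edge are skipped with a logged warning.
    An event-free recording yields an empty (0-epoch) set.
    """
    n_pre = int(round(pre_ms / 1000.0 * rec.fs))
    n_post = int(round(post_ms / 1000.0 * rec.fs))
    n_len = n_pre + n_post
    epochs, conditions = [], []
    for onset, label in rec.events:
        onset = int(onset)
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > rec.n_samples:
            logger.warning("event at sample %d (%s) skipped: window "
                           "[%d, %d) outside recording", onset, label,
                           start, stop)
            continue
        epochs.append(rec.data[:, start:stop])
        conditions.append(label)
    if epochs:
        data = np.stack(epochs)
    else:
        data = np.empty((0, rec.n_channels, n_len))
    return EpochSet(data, rec.fs, list(rec.channel_names),
                    np.array(conditions, dtype=object), pre_ms)


def reject_peak_to_peak(eps: EpochSet, threshold=150.0) -> EpochSet:
    """Stage 1: reject epochs whose peak-to-peak amplitude exceeds 150 μV.

    The per-epoch statistic is the maximum over channels of the within-
    epoch (max − min); rejection uses a strict ``>`` so an epoch at
    exactly the threshold is kept.
    """
    if eps.n_epochs == 0:
        raise ValueError("empty epoch set")
    out = eps.copy()
    p2p = out.data.max(axis=2) - out.data.min(axis=2)  # (n_epochs, n_channels)
    worst = p2p.max(axis=1)
    hit = (worst > threshold) & (out.status == KEPT)
    out.status[hit] = REJECTED_P2P
    if hit.any():
        logger.info("peak-to-peak rejection: %d of %d epochs (threshold "
                    "%.1f μV)", int(hit.sum()), out.n_epochs, threshold)
    return out


def epoch_sd(eps: EpochSet, per_channel=False):
    """Per-epoch standard deviation, pooled over channels × samples.

    With ``per_channel=True`` the result is (n_epochs, n_channels)
    instead of one pooled SD per epoch.
    """
    if per_channel:
        return eps.data.std(axis=2)
    return eps.data.reshape(eps.n_epochs, -1).std(axis=1)


def reject_sd(eps: EpochSet, hi_factor=3.0, lo_factor=1.0 / 3.0,
              iterative=True, per_channel=False) -> EpochSet:
    """Stage 2: reject epochs with outlying standard deviation.

    An epoch is rejected when its SD is strictly greater than
    ``hi_factor`` times, or strictly lower than ``lo_factor`` times, the
    mean SD over the currently non-rejected epochs.  Because the
    reference mean itself depends on which epochs are rejected, the rule
    is iterated to a fixed point starting from the stage-1 survivors;
    ``iterative=False`` gives the single-pass reading instead.
    """
    out = eps.copy()
    kept = out.status == KEPT
    if kept.sum() < 2:
        raise ValueError("need at least 2 kept epochs for the SD criterion")
    sd = epoch_sd(out, per_channel=per_channel)
    while True:
        ref = sd[kept].mean(axis=0)
        if per_channel:
            viol = ((sd > hi_factor * ref) | (sd < lo_factor * ref)).any(axis=1)
        else:
            viol = (sd > hi_factor * ref) | (sd < lo_factor * ref)
        new = viol & kept
        if not new.any():
            break
        out.status[new] = REJECTED_SD
        kept = out.status == KEPT
        if not iterative or not kept.any():
            break
    n_rej = int((out.status == REJECTED_SD).sum())
    if n_rej:
        logger.info("SD-ratio rejection: %d epochs", n_rej)
    if not (out.status == KEPT).any():
        logger.warning("SD-ratio rejection removed every epoch")
    return out


def apply_manual_mask(eps: EpochSet, mask=None) -> EpochSet:
    """Stage 3: user-supplied mask standing in for visual inspection.

    ``mask[i]`` True marks epoch ``i`` for rejection; epochs already
    rejected by an earlier stage keep their original status.  Passing
    ``mask=None`` makes the stage a no-op.
    """
    out = eps.copy()
    if mask is None:
        return out
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != out.n_epochs:
        raise ValueError(f"mask length {len(mask)} != n_epochs {out.n_epochs}")
    hit = mask & (out.status == KEPT)
    out.status[hit] = REJECTED_MANUAL
    return out


class InclusionDecision:
    """Per-participant inclusion decision with the counts behind it."""

    def __init__(self, included, counts, reason=""):
        self.included = bool(included)
        self.counts = dict(counts)
        self.reason = reason

    def __repr__(self):
        tag = "included" if self.included else f"excluded ({self.reason})"
        return f"InclusionDecision({tag}, counts={self.counts})"


def check_inclusion(eps: EpochSet, conditions, min_epochs=20):
    """Participant inclusion rule: ≥ ``min_epochs`` kept epochs per condition.

    The bound is inclusive — exactly 20 kept epochs in each condition is
    enough.  A condition absent from the epoch set excludes the
    participant outright.
    """
    counts = {c: eps.kept_count(c) for c in conditions}
    for cond in conditions:
        if not (eps.conditions == cond).any():
            return InclusionDecision(False, counts,
                                     f"condition {cond!r} missing")
    low = [c for c, n in counts.items() if n < min_epochs]
    if low:
        return InclusionDecision(
            False, counts,
            "fewer than %d kept epochs in %s" % (min_epochs, ", ".join(low)))
    return InclusionDecision(True, counts)


def reject_epochs(eps: EpochSet, p2p_threshold=150.0, hi_factor=3.0,
                  lo_factor=1.0 / 3.0, iterative=True, manual_mask=None):
    """Run the full three-stage rejection chain in the prescribed order."""
    out = reject_peak_to_peak(eps, p2p_threshold)
    if (out.status == KEPT).sum() >= 2:
        out = reject_sd(out, hi_factor, lo_factor, iterative=iterative)
    out = apply_manual_mask(out, manual_mask)
    return out
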