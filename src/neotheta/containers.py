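"""Core data containers shared across pipeline stages.

Amplitudes are in microvolts (μV) throughout.  Time axes are in
milliseconds relative to stimulus onset unless a variable name says
otherwise; sample indices are integers into the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical 10-channel montage (international 10-20 positions) used for
#: newborn auditory recordings; T7/T8 are the modern names of T3/T4.
CANONICAL_CHANNELS = ("F7", "F3", "FZ", "F4", "F8", "T7", "C3", "CZ", "C4", "T8")

# Per-epoch status labels.  An epoch's status is set once: the first
# rejection stage that fires wins.
KEPT = "kept"
REJECTED_P2P = "rejected_p2p"
REJECTED_SD = "rejected_sd"
REJECTED_MANUAL = "rejected_manual"
ALL_STATUSES = (KEPT, REJECTED_P2P, REJECTED_SD, REJECTED_MANUAL)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with stimulus-onset event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels (10-20 names for real recordings).
    events : list of (int, str)
        ``(onset_sample, condition_label)`` pairs, onset within the
        recording.
    """

    data: np.ndarray
    fs: float
    channel_names: list
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel labels must be unique")
        for onset, _ in self.events:
            if not 0 <= int(onset) < self.n_samples:
                raise ValueError(f"event onset {onset} outside recording")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    def channel_index(self, name):
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self):
        return EEGRecording(self.data.copy(), self.fs, list(self.channel_names),
                            [tuple(e) for e in self.events])


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch condition and rejection status.

    ``data`` has shape (n_epochs, n_channels, n_samples); ``t0_offset_ms``
    is the position of stimulus onset within each epoch (the pre-stimulus
    span).  ``status`` holds one of :data:`ALL_STATUSES` per epoch.
    """

    data: np.ndarray
    fs: float
    channel_names: list
    conditions: np.ndarray
    t0_offset_ms: float
    status: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        self.channel_names = list(self.channel_names)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if len(self.conditions) != self.n_epochs:
            raise ValueError("conditions length does not match epochs")
        if self.status is None:
            self.status = np.array([KEPT] * self.n_epochs, dtype=object)
        else:
            self.status = np.asarray(self.status, dtype=object)
            if len(self.status) != self.n_epochs:
                raise ValueError("status length does not match epochs")
        bad = set(self.status) - set(ALL_STATUSES)
        if bad:
            raise ValueError(f"unknown status values: {bad}")

    @property
    def n_epochs(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[2]

    def channel_index(self, name):
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def kept_mask(self, condition=None):
        mask = self.status == KEPT
        if condition is not None:
            mask &= self.conditions == condition
        return mask

    def kept_count(self, condition=None):
        return int(self.kept_mask(condition).sum())

    def status_counts(self):
        """Mapping status -> count; counts always sum to n_epochs."""
        return {s: int((self.status == s).sum()) for s in ALL_STATUSES}

    def copy(self):
        return EpochSet(self.data.copy(), self.fs, list(self.channel_names),
                        self.conditions.copy(), self.t0_offset_ms,
                        self.status.copy())


RAW = "raw"
CORRECTED = "corrected"


@dataclass
class TFRMap:
    """Frequency × time map of spectral amplitude (μV, not power).

    ``baseline_state`` is a two-state machine: maps start ``"raw"``
    (amplitude ≥ 0) and become ``"corrected"`` after baseline
    subtraction (values may then be negative).
    """

    amplitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_state: str = RAW
    channel: str = None
    condition: str = None
    participant_id: str = None

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.amplitude.shape != (len(self.freqs), len(self.times)):
            raise ValueError("amplitude shape does not match freq/time axes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.baseline_state not in (RAW, CORRECTED):
            raise ValueError(f"bad baseline_state {self.baseline_state!r}")

    def copy(self):
        return TFRMap(self.amplitude.copy(), self.freqs.copy(),
                      self.times.copy(), self.baseline_state,
                      self.channel, self.condition, self.participant_id)


@dataclass
class GroupTFR:
    """Stack of baseline-corrected participant TFR maps for two conditions.

    ``amplitudes[cond]`` has shape (n_participants, n_freqs, n_times);
    participant order is aligned across conditions, so the paired
    difference ``amplitudes[a] - amplitudes[b]`` is meaningful row-wise.
    """

    amplitudes: dict
    conditions: tuple
    participant_ids: list
    freqs: np.ndarray
    times: np.ndarray
    channel: str = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        shape = (len(self.participant_ids), len(self.freqs), len(self.times))
        for cond in self.conditions:
            arr = np.asarray(self.amplitudes[cond], dtype=float)
            if arr.shape != shape:
                raise ValueError(f"condition {cond!r} stack shape {arr.shape} "
                                 f"!= expected {shape}")
            self.amplitudes[cond] = arr
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")

    @property
    def n_participants(self):
        return len(self.participant_ids)

    def differences(self):
        """Per-participant (condition A − condition B) maps, shape (n, F, T)."""
        a, b = self.conditions
        return self.amplitudes[a] - self.amplitudes[b]


@dataclass
class Cluster:
    """One suprathreshold connected component of the t map."""

    mask: np.ndarray          # boolean (n_freqs, n_times)
    sign: int                 # +1 or -1
    mass: float               # sum of t over the mask (sign-consistent)
    p_value: float = None

    @property
    def significant(self):
        return self.p_value is not None and self.p_value <= 0.05


@dataclass
class ClusterResult:
    """Output of the cluster-based permutation test for one channel."""

    t_map: np.ndarray
    df: int
    threshold: float
    clusters: list
    null_max_mass: np.ndarray
    n_perm: int
    exact: bool
    alpha: float
    freqs: np.ndarray = None
    times: np.ndarray = None
    channel: str = None
    eta_sq_map: np.ndarray = None

    def significant_clusters(self, alpha=None):
        alpha = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value <= alpha]

    def min_p(self):
        return min((c.p_value for c in self.clusters), default=1.0)
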