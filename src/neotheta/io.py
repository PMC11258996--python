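"""Readers and writers for recordings, epochs, TFR maps and tables.

The internal interchange container is HDF5: recordings are stored as
``/data`` (channels × samples, float32, μV) plus ``/events`` with
``fs`` and ``channel_names`` attributes.  BrainVision (.vhdr/.vmrk/.eeg)
and EDF recordings are read through ``mne`` and converted to μV;
writing those vendor formats is out of scope.
"""

from __future__ import annotations

import json
import logging
import os

import h5py
import numpy as np
import pandas as pd

from .containers import (CANONICAL_CHANNELS, EEGRecording, EpochSet, RAW,
                         TFRMap)

logger = logging.getLogger(__name__)

VOCAB_CSV_COLUMNS = ("participant_id", "comp12", "prod12", "comp18", "prod18")


# ---------------------------------------------------------------------------
# HDF5 recording container

def write_recording_h5(rec: EEGRecording, path):
    """Write a recording to the documented HDF5 layout."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data.astype(np.float32))
        onsets = np.array([int(o) for o, _ in rec.events], dtype=np.int64)
        codes = np.array([str(c) for _, c in rec.events],
                         dtype=h5py.string_dtype())
        ev = fh.create_group("events")
        ev.create_dataset("onset_sample", data=onsets)
        ev.create_dataset("code", data=codes)
        fh.attrs["fs"] = float(rec.fs)
        fh.attrs["channel_names"] = [str(c) for c in rec.channel_names]


def read_recording_h5(path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()].astype(float)
        onsets = fh["events/onset_sample"][()]
        codes = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in fh["events/code"][()]]
        fs = float(fh.attrs["fs"])
        names = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in fh.attrs["channel_names"]]
    events = list(zip((int(o) for o in onsets), codes))
    return EEGRecording(data, fs, names, events)


# ---------------------------------------------------------------------------
# Vendor formats (read-only, via mne)

def _reorder_canonical(rec: EEGRecording) -> EEGRecording:
    """Reorder channels to the canonical 10-channel list when present."""
    upper = [c.upper() for c in rec.channel_names]
    if set(CANONICAL_CHANNELS) <= set(upper):
        idx = [upper.index(c) for c in CANONICAL_CHANNELS]
        rec = EEGRecording(rec.data[idx], rec.fs, list(CANONICAL_CHANNELS),
                           rec.events)
    return rec


def _events_from_annotations(raw, condition_map):
    """Map mne annotations to (onset_sample, condition) via a marker map.

    ``condition_map`` maps marker codes (e.g. ``"S  1"``) to condition
    labels; descriptions are matched after stripping a ``"Stimulus/"``
    prefix.  Unmapped markers (new-segment etc.) are ignored.
    """
    events = []
    if condition_map is None:
        condition_map = {}
    for onset, desc in zip(raw.annotations.onset,
                           raw.annotations.description):
        code = desc.split("Stimulus/")[-1].strip()
        label = condition_map.get(code, condition_map.get(desc))
        if label is None:
            continue
        events.append((int(round(onset * raw.info["sfreq"])), label))
    return events


def read_brainvision(vhdr_path, condition_map=None) -> EEGRecording:
    """Read a BrainVision triplet; data returned in μV."""
    import mne

    if not os.path.exists(vhdr_path):
        raise FileNotFoundError(vhdr_path)
    marker = _brainvision_sidecar(vhdr_path, "MarkerFile")
    if marker is not None and not os.path.exists(
            os.path.join(os.path.dirname(vhdr_path), marker)):
        raise FileNotFoundError(f"marker file {marker!r} referenced by "
                                f"{vhdr_path} is missing")
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    rec = EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"],
                       list(raw.ch_names),
                       _events_from_annotations(raw, condition_map))
    return _reorder_canonical(rec)


def _brainvision_sidecar(vhdr_path, key):
    with open(vhdr_path, "r", encoding="latin-1") as fh:
        for line in fh:
            if line.strip().startswith(key + "="):
                return line.strip().split("=", 1)[1]
    return None


def read_edf(path, condition_map=None) -> EEGRecording:
    """Read an EDF recording; data returned in μV."""
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rec = EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"],
                       list(raw.ch_names),
                       _events_from_annotations(raw, condition_map))
    return _reorder_canonical(rec)


def read_eeg(path, fmt=None, condition_map=None) -> EEGRecording:
    """Dispatch on format (brainvision | edf | hdf5), inferring from the
    extension when ``fmt`` is not given."""
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = {".vhdr": "brainvision", ".edf": "edf",
               ".h5": "hdf5", ".hdf5": "hdf5"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer EEG format from {path!r}")
    if fmt == "brainvision":
        return read_brainvision(path, condition_map)
    if fmt == "edf":
        return read_edf(path, condition_map)
    if fmt == "hdf5":
        return read_recording_h5(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Epochs and TFR containers

def write_epochs_h5(eps: EpochSet, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=eps.data.astype(np.float32))
        sd = h5py.string_dtype()
        fh.create_dataset("conditions",
                          data=np.array([str(c) for c in eps.conditions],
                                        dtype=sd))
        fh.create_dataset("status",
                          data=np.array([str(s) for s in eps.status],
                                        dtype=sd))
        fh.attrs["fs"] = float(eps.fs)
        fh.attrs["t0_offset_ms"] = float(eps.t0_offset_ms)
        fh.attrs["channel_names"] = [str(c) for c in eps.channel_names]


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        dec = lambda v: v.decode() if isinstance(v, bytes) else str(v)
        return EpochSet(fh["data"][()].astype(float), float(fh.attrs["fs"]),
                        [dec(c) for c in fh.attrs["channel_names"]],
                        np.array([dec(c) for c in fh["conditions"][()]],
                                 dtype=object),
                        float(fh.attrs["t0_offset_ms"]),
                        np.array([dec(s) for s in fh["status"][()]],
                                 dtype=object))


def epoch_status_table(eps: EpochSet) -> pd.DataFrame:
    return pd.DataFrame({"epoch": np.arange(eps.n_epochs),
                         "condition": eps.conditions,
                         "status": eps.status})


def write_tfr_h5(tfr: TFRMap, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("amplitude", data=tfr.amplitude)
        fh.create_dataset("freqs", data=tfr.freqs)
        fh.create_dataset("times", data=tfr.times)
        fh.attrs["baseline_state"] = tfr.baseline_state
        for key in ("channel", "condition", "participant_id"):
            val = getattr(tfr, key)
            if val is not None:
                fh.attrs[key] = str(val)


def read_tfr_h5(path) -> TFRMap:
    with h5py.File(path, "r") as fh:
        kw = {key: fh.attrs.get(key) for key in
              ("channel", "condition", "participant_id")}
        kw = {k: (v if v is None else str(v)) for k, v in kw.items()}
        return TFRMap(fh["amplitude"][()], fh["freqs"][()], fh["times"][()],
                      str(fh.attrs["baseline_state"]), **kw)


# ---------------------------------------------------------------------------
# Tables and manifests

def write_vocab_csv(tbl: pd.DataFrame, path):
    """Vocabulary CSV with the documented column order; empty cell = missing."""
    out = tbl.loc[:, list(VOCAB_CSV_COLUMNS)
                  if "discrimination_0m" not in tbl.columns
                  else ["participant_id", "discrimination_0m", "comp12",
                        "prod12", "comp18", "prod18"]]
    out.to_csv(path, index=False)


def read_vocab_csv(path) -> pd.DataFrame:
    tbl = pd.read_csv(path)
    if "participant_id" not in tbl.columns:
        raise ValueError("vocabulary CSV must have a participant_id column")
    if tbl["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    return tbl


def write_manifest(manifest: dict, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
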