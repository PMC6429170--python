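"""Session I/O: EDF signal files, event tables, and run manifests.

Sessions are interchanged as one EDF file (16-bit samples with per-channel
physical scaling, the standard clinical EEG container) plus a plain-text
events CSV with columns ``onset_sample`` (0-based), ``tag``,
``artifact_truth`` and ``user_id``.  Epoch windows are half-open
``[onset, onset + epoch_len)``.  Only epoch windows are materialized, written
back to back as a continuous record.

Writing uses a small built-in EDF encoder; reading goes through
``mne.io.read_raw_edf`` so every file round-trips through an independent
implementation of the format.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = ["write_session", "read_session", "write_manifest"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, channel_names, fs: float,
              record_len: int) -> None:
    """Write continuous multichannel data (channels x samples, µV) as EDF.

    ``record_len`` samples per channel per data record; the total length must
    be a multiple of it.  Each channel gets a symmetric physical range covering
    its data, so quantization error is bounded by range / 2^16.
    """
    n_ch, n_samp = data.shape
    if n_samp % record_len:
        raise ValueError("total samples must be a multiple of record_len")
    n_records = n_samp // record_len
    duration = record_len / fs

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max)
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_max)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad(f"{duration:g}", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(name, 16) for name in channel_names],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{phys_min[c]:g}", 8) for c in range(n_ch)],
        [_pad(f"{phys_max[c]:g}", 8) for c in range(n_ch)],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(record_len), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: per record, channels consecutively
        rec = digital.reshape(n_ch, n_records, record_len)
        for r in range(n_records):
            fh.write(rec[:, r, :].tobytes())


def write_session(epochs: EpochSet, edf_path, events_path,
                  profile=None, profile_path=None) -> None:
    """Write one session as EDF + events CSV (and optionally the profile JSON).

    Epochs are concatenated back to back; the events CSV records each epoch's
    0-based onset sample, tag, simulator artifact ground truth and user id.
    """
    n, n_ch, L = epochs.data.shape
    continuous = np.transpose(epochs.data, (1, 0, 2)).reshape(n_ch, n * L)
    write_edf(edf_path, continuous, list(epochs.channel_names), epochs.fs,
              record_len=L)
    pd.DataFrame({
        "onset_sample": np.arange(n) * L,
        "tag": epochs.tags,
        "artifact_truth": epochs.artifact_truth.astype(int),
        "user_id": np.full(n, epochs.user_id),
    }).to_csv(events_path, index=False)
    if profile is not None and profile_path is not None:
        profile.to_json(profile_path)


def read_session(edf_path, events_path) -> EpochSet:
    """Read a session written by :func:`write_session` back into an EpochSet.

    Signals are loaded with MNE and returned in µV.  The epoch length is taken
    from the spacing of the onset samples (all epochs equal length, half-open
    windows).  Raises on empty event tables, non-monotone onsets, or epochs
    extending beyond the recording.
    """
    import mne

    events = pd.read_csv(events_path)
    if len(events) == 0:
        raise ValueError("no epochs: the events table is empty")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) > 1:
        diffs = np.diff(onsets)
        if (diffs <= 0).any():
            raise ValueError("event onsets must be strictly increasing")
        if np.unique(diffs).size != 1:
            raise ValueError("event onsets must be equally spaced epochs")
        epoch_len = int(diffs[0])
    else:
        epoch_len = None

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # MNE returns volts for µV channels
    n_times = data.shape[1]
    if epoch_len is None:
        epoch_len = n_times - int(onsets[0])
    if onsets[-1] + epoch_len > n_times:
        raise ValueError(
            f"event at sample {onsets[-1]} extends beyond the recording "
            f"({n_times} samples)"
        )
    epochs = np.stack([data[:, o:o + epoch_len] for o in onsets])
    user_id = int(events["user_id"].iloc[0]) if "user_id" in events else 0
    artifact = (events["artifact_truth"].to_numpy().astype(bool)
                if "artifact_truth" in events else np.zeros(len(events), bool))
    return EpochSet(
        data=epochs,
        tags=events["tag"].to_numpy(),
        user_id=user_id,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        artifact_truth=artifact,
    )


def write_manifest(path, config: dict) -> None:
    """Serialize a run's full configuration (stage parameters + seeds)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
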