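"""Bandpass filtering, blink rejection, and observation-vector construction.

The evaluation pipeline reduces each epoch to the concatenation of a small set
of informative electrodes (default P7 + P8), after a 0.5–30 Hz zero-phase
bandpass and peak-to-peak EOG artifact rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .montage import EOG_CHANNELS
from .simulate import EpochSet

__all__ = ["ObservationSet", "bandpass", "reject_artifacts", "select_concat"]

# Epochs shorter than this cannot be padded/filtered stably.
MIN_FILTER_LEN = 64


@dataclass
class ObservationSet:
    """Per-epoch observation vectors: selected channels concatenated.

    With the default two electrodes and 1000-sample epochs each row is the
    2000-dimensional vector the density models are built on.
    """

    vectors: np.ndarray          # (n_epochs, D), µV
    tags: np.ndarray             # (n_epochs,)
    user_id: int
    channels: Sequence[str]
    epoch_len: int
    fs: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.tags = np.asarray(self.tags, dtype=int)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (epochs x D)")
        if self.vectors.shape[0] != self.tags.shape[0]:
            raise ValueError("vectors/tags length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def bandpass(epochs: EpochSet, lo: float = 0.5, hi: float = 30.0,
             order: int = 4) -> EpochSet:
    """Zero-phase Butterworth bandpass applied identically to every channel.

    The filter is applied forward-backward (``sosfiltfilt``), so ERP component
    latencies are preserved.  Each epoch is reflect-padded by three time
    constants of the low cutoff (capped at the epoch length) before filtering.
    """
    if not (0 < lo < hi < epochs.fs / 2):
        raise ValueError("need 0 < lo < hi < Nyquist")
    n = epochs.n_samples
    if n < MIN_FILTER_LEN:
        raise ValueError(
            f"epoch of {n} samples too short for stable filtering; "
            f"minimum is {MIN_FILTER_LEN} samples"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.fs, output="sos")
    padlen = min(n - 1, int(round(3.0 * epochs.fs / (2.0 * np.pi * lo))))
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1,
                                  padtype="even", padlen=padlen)
    return EpochSet(
        data=filtered,
        tags=epochs.tags.copy(),
        user_id=epochs.user_id,
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        artifact_truth=epochs.artifact_truth.copy(),
    )


def reject_artifacts(
    epochs: EpochSet,
    eog_channels: Sequence[str] = tuple(EOG_CHANNELS),
    threshold: float = 100.0,
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose EOG peak-to-peak exceeds ``threshold`` µV.

    Returns the surviving epochs (samples untouched) and the rejected epoch
    indices.  Raises if every epoch is rejected, since the downstream
    evaluation is undefined on an empty set.
    """
    idx = [epochs.channel_index(c) for c in eog_channels]
    ptp = epochs.data[:, idx, :].max(axis=-1) - epochs.data[:, idx, :].min(axis=-1)
    rejected = np.flatnonzero((ptp > threshold).any(axis=1))
    if rejected.size == epochs.n_epochs:
        raise ValueError("all epochs rejected; lower the threshold or check the EOG channels")
    keep = np.setdiff1d(np.arange(epochs.n_epochs), rejected)
    return epochs.subset(keep), rejected


def select_concat(epochs: EpochSet,
                  channels: Sequence[str] = ("P7", "P8")) -> ObservationSet:
    """Concatenate the named channels, in order, into one vector per epoch."""
    idx = [epochs.channel_index(c) for c in channels]
    n = epochs.n_epochs
    vectors = epochs.data[:, idx, :].reshape(n, len(idx) * epochs.n_samples)
    return ObservationSet(
        vectors=vectors,
        tags=epochs.tags.copy(),
        user_id=epochs.user_id,
        channels=list(channels),
        epoch_len=epochs.n_samples,
        fs=epochs.fs,
    )
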