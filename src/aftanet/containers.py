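"""Core in-memory containers for continuous recordings and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawRecording", "EpochTensor", "LabeledEpochSet"]


@dataclass
class RawRecording:
    """A continuous multichannel signal in microvolts.

    data : array of shape (n_channels, n_samples)
    fs : sampling rate in Hz
    channel_names : ordered channel labels, one per row
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"CH{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochTensor:
    """One fixed-length preprocessed window, shape (C, T), in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"CH{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LabeledEpochSet:
    """Epochs with one integer class label each."""

    epochs: list[EpochTensor]
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.epochs) != len(self.labels):
            raise ValueError("epochs and labels must have equal length")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels outside declared class range")

    def __len__(self) -> int:
        return len(self.epochs)

    def as_array(self) -> np.ndarray:
        """Stack epochs into an (n, C, T) array."""
        return np.stack([e.data for e in self.epochs])

    def subset(self, idx: np.ndarray) -> "LabeledEpochSet":
        idx = np.asarray(idx)
        return LabeledEpochSet([self.epochs[i] for i in idx],
                               self.labels[idx], list(self.class_names))
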