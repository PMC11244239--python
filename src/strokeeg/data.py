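"""Core containers: continuous recordings and fixed-length epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .montage import CHANNELS


@dataclass
class EegRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data
        ``[n_channels x n_samples]`` signal in microvolts.
    channel_names
        Electrode names in the frozen 10-20 order.
    fs
        Sampling rate in Hz.
    subject_id
        Identifier for provenance.
    label
        ``1`` for ischemic stroke, ``0`` for non-stroke control,
        ``None`` when unknown.
    """

    data: np.ndarray
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS))
    fs: float = 256.0
    subject_id: str = "unknown"
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be 2-D [channels x samples]")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EegRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows cut from one recording."""

    epochs: np.ndarray  # [n_epochs x channels x samples_per_epoch]
    fs: float
    epoch_length_s: float
    channel_names: Sequence[str] = field(default_factory=lambda: list(CHANNELS))
    subject_id: str = "unknown"
    label: int | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ConfigurationError("epochs must be 3-D [epochs x channels x samples]")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ConfigurationError(
                f"samples per epoch {self.epochs.shape[2]} != fs*epoch_length {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]
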