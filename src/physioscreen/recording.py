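"""Core container for uniformly sampled physiological signal channels."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChannelRecording:
    """One uniformly sampled signal channel.

    Parameters
    ----------
    values : ndarray
        1-D array of samples (PPG in arbitrary units, EDA in µS,
        temperature in °C).
    fs : float
        Sampling rate in Hz.
    kind : str
        Channel kind, one of ``"ppg"``, ``"eda"``, ``"temperature"`` or a
        derived kind such as ``"temperature_derivative"``.
    start_time : float
        Time of the first sample in seconds, relative to the recording it
        was cut from (0 for freshly simulated phases).
    """

    values: np.ndarray
    fs: float
    kind: str
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ChannelRecording values must be 1-D")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Spanned time (n-1)/fs in seconds."""
        return max(self.n_samples - 1, 0) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (absolute, including ``start_time``)."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def replace(self, **kwargs) -> "ChannelRecording":
        return dataclasses.replace(self, **kwargs)
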