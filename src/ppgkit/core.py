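"""Core in-memory containers for PPG signals and pulses.

A :class:`PPGSignal` is a uniformly sampled single-channel
photoplethysmogram: an amplitude array in arbitrary units (PPG devices are
uncalibrated), its sampling rate, a time offset, and free-form metadata
(subject id, group label, activity, ...). A :class:`PulseWave` is one
segmented beat; an :class:`EnsemblePulse` is the pointwise mean of
time-normalized beats with its dispersion envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PPGSignal:
    """Uniformly sampled PPG amplitude series.

    Parameters
    ----------
    samples
        Amplitude values, arbitrary units. Must be finite and length >= 2.
    fs_hz
        Sampling frequency in Hz, > 0.
    t0_s
        Time of the first sample in seconds (offset within a parent
        recording; 0 for a fresh recording).
    meta
        Free-form key/value metadata.
    """

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("PPGSignal requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPGSignal samples must be finite")
        if not (self.fs_hz > 0):
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0_s``."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


@dataclass
class PulseWave:
    """A single segmented beat.

    ``onset_index`` is the sample index of the pulse onset in the parent
    signal, so fiducial times can be mapped back to recording time.
    """

    samples: np.ndarray
    fs_hz: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EnsemblePulse:
    """Pointwise mean of time-normalized beats plus dispersion envelope."""

    mean_shape: np.ndarray
    sd_shape: np.ndarray
    n_beats: int
    fs_equivalent: float

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.sd_shape = np.asarray(self.sd_shape, dtype=float)
        if self.mean_shape.shape != self.sd_shape.shape:
            raise ValueError("mean and SD envelopes must have equal length")
        if self.n_beats < 1:
            raise ValueError("an ensemble requires at least one beat")

    def as_pulse(self) -> PulseWave:
        """View the mean shape as a PulseWave at the equivalent rate."""
        return PulseWave(self.mean_shape, self.fs_equivalent)
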