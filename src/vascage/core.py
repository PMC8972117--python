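"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawRecording", "BeatSegment", "NormalizedBeat", "N_BEAT_SAMPLES"]

#: every beat is resampled onto this many uniformly spaced points
N_BEAT_SAMPLES = 1000


@dataclass
class RawRecording:
    """A sampled single-channel PPG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in arbitrary units.
    fs : float
        Sampling frequency in Hz (> 0).
    subject_id : str, optional
        Identifier of the subject the signal was recorded from.
    age : float, optional
        Subject age in years, if known.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array with at least 2 points")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Total length of the recording in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatSegment:
    """One beat cut from a recording on the half-open span [onset, next onset)."""

    samples: np.ndarray
    fs: float
    onset_index: int
    subject_id: str | None = None
    beat_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.onset_index < 0:
            raise ValueError("onset_index must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        """Beat length in seconds (number of samples / fs)."""
        return self.samples.size / self.fs

    @property
    def onset_s(self) -> float:
        return self.onset_index / self.fs


@dataclass
class NormalizedBeat:
    """A beat resampled to ``N_BEAT_SAMPLES`` points, amplitude in [0, 1].

    ``duration`` keeps the original beat length in seconds so that
    time-domain features can be mapped back from the normalized grid;
    the resampling itself erases the sampling rate.
    """

    samples: np.ndarray
    duration: float
    source: BeatSegment | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != N_BEAT_SAMPLES:
            raise ValueError(
                f"normalized beat must have {N_BEAT_SAMPLES} samples, "
                f"got {self.samples.size}"
            )
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    @property
    def times(self) -> np.ndarray:
        """Time grid in seconds: uniform over [0, duration), matching the
        original sample grid convention t_k = k / fs."""
        n = self.samples.size
        return np.linspace(0.0, self.duration * (n - 1) / n, n)
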