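"""Beat-level preprocessing: bandpass filtering, pulse-onset detection,
segmentation, abnormal-beat rejection, and resampling/normalization.

The stages mirror the standard pulse-wave-analysis front end: a 0.5-10 Hz
linear-phase FIR bandpass removes baseline wander and high-frequency noise,
pulse onsets are located as the local minima preceding each systolic
upstroke, beats are cut on half-open inter-onset spans, irregular beats are
dropped against recording-level medians, and each surviving beat is
linearly interpolated onto a 1000-point grid and min-max normalized to
[0, 1] (its original duration in seconds is retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BeatSegment, N_BEAT_SAMPLES, NormalizedBeat, RawRecording

__all__ = [
    "bandpass_filter",
    "detect_onsets",
    "segment_beats",
    "reject_abnormal",
    "resample_normalize",
    "RejectionLog",
]


def _design_fir(fs: float, low: float, high: float, transition: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR bandpass; the tap count is chosen so
    the transition band at the low edge is about ``transition`` Hz."""
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def bandpass_filter(
    rec: RawRecording,
    low: float = 0.5,
    high: float = 10.0,
    transition: float = 0.3,
) -> RawRecording:
    """Apply the 0.5-10 Hz FIR bandpass with zero net group delay.

    The FIR is linear-phase; filtering is done by centred convolution with
    reflected edge padding, so features and onsets are not shifted in time.
    Requires ``fs`` > 2*high (passband must fit below Nyquist).
    """
    if rec.fs <= 2.0 * high:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {high} Hz passband edge (need fs > {2*high})"
        )
    taps = _design_fir(rec.fs, low, high, transition)
    x = rec.samples
    # cap the filter length for very short signals (keeps reflect-padding valid)
    if taps.size > 2 * x.size - 1:
        warnings.warn(
            "signal shorter than designed FIR; truncating filter taps",
            stacklevel=2,
        )
        n = 2 * (x.size // 2) - 1
        taps = sps.firwin(max(n, 21), [low, high], pass_zero=False, fs=rec.fs)
    pad = taps.size // 2
    xp = np.pad(x, pad, mode="reflect")
    y = np.convolve(xp, taps, mode="valid")
    assert y.size == x.size
    return RawRecording(samples=y, fs=rec.fs, subject_id=rec.subject_id, age=rec.age)


def detect_onsets(rec: RawRecording, min_peak_distance_s: float = 0.3) -> np.ndarray:
    """Locate pulse onsets on a (filtered) recording.

    A pulse onset is the local minimum preceding a systolic upslope.
    Maximal-upslope points are found first (the systolic rise is several
    times steeper than any diastolic rise; the gate uses a high percentile
    so one surged beat cannot mask the rest, with a refractory of 0.55
    autocorrelation periods); the onset of each beat is the argmin of the
    valley within 0.4 periods before its upstroke.  Returns strictly
    increasing sample indices; a too-short or flat signal yields an empty
    array with a warning rather than an exception.
    """
    x = rec.samples
    span = float(np.ptp(x)) if x.size else 0.0
    if x.size < int(0.5 * rec.fs) or span <= 0 or not np.isfinite(span):
        warnings.warn("signal too short or flat; no onsets detected", stacklevel=2)
        return np.array([], dtype=int)

    # beat period from the autocorrelation (robust against prominent
    # diastolic peaks)
    xm = x - np.mean(x)
    ac = np.correlate(xm, xm, mode="full")[xm.size - 1 :]
    lo, hi = int(0.4 * rec.fs), min(int(2.0 * rec.fs), ac.size - 1)
    if hi > lo + 1:
        period = lo + int(np.argmax(ac[lo:hi]))
    else:
        period = int(0.8 * rec.fs)

    # one maximal-upslope point per beat: the systolic upstroke is several
    # times steeper than any diastolic rise, so gate on slope and greedily
    # enforce a 0.55-period refractory (steeper upstroke wins)
    d = np.gradient(x)
    distance = max(int(min_peak_distance_s * rec.fs), 1)
    cand, _ = sps.find_peaks(d, distance=distance)
    if cand.size == 0:
        warnings.warn("no systolic upstrokes found; no onsets detected", stacklevel=2)
        return np.array([], dtype=int)
    # gate against a high percentile, not the max: a single surged beat must
    # not lift the threshold above the normal upstrokes
    thr = 0.45 * float(np.percentile(d[cand], 85))
    upstrokes = cand[d[cand] >= thr]
    if upstrokes.size == 0:
        warnings.warn("no systolic upstrokes found; no onsets detected", stacklevel=2)
        return np.array([], dtype=int)
    min_dist = 0.55 * period
    kept: list[int] = []
    for p in sorted(upstrokes, key=lambda q: -d[q]):
        if all(abs(p - k) >= min_dist for k in kept):
            kept.append(int(p))
    upstrokes = np.array(sorted(kept), dtype=int)

    if upstrokes.size >= 2:
        median_ibi = float(np.median(np.diff(upstrokes)))
    else:
        median_ibi = float(period)

    # onset = minimum of the valley immediately preceding each upstroke;
    # the search window stays clear of the dicrotic notch a full period back
    back = int(0.4 * period)
    onsets = []
    for i, p in enumerate(upstrokes):
        start = max(upstrokes[i - 1], p - back) if i > 0 else max(0, p - back)
        if p - start < 2:
            continue
        onsets.append(start + int(np.argmin(x[start:p])))
    onsets = np.array(sorted(set(onsets)), dtype=int)
    # refractory: drop onsets implausibly close to their predecessor
    if onsets.size >= 3:
        min_gap = 0.4 * float(np.median(np.diff(onsets)))
        keep = [0]
        for j in range(1, onsets.size):
            if onsets[j] - onsets[keep[-1]] >= min_gap:
                keep.append(j)
        onsets = onsets[keep]
    return onsets


def segment_beats(rec: RawRecording, onsets: np.ndarray) -> list[BeatSegment]:
    """Cut the recording into half-open inter-onset spans.

    ``k`` onsets yield ``k - 1`` contiguous, non-overlapping segments;
    fewer than 2 onsets yield an empty list.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        return []
    segments = []
    for i in range(onsets.size - 1):
        a, b = int(onsets[i]), int(onsets[i + 1])
        segments.append(
            BeatSegment(
                samples=rec.samples[a:b],
                fs=rec.fs,
                onset_index=a,
                subject_id=rec.subject_id,
                beat_index=i,
            )
        )
    return segments


@dataclass
class RejectionLog:
    """Per-beat record of which rejection rule fired (empty string = kept)."""

    entries: pd.DataFrame

    def n_rejected(self) -> int:
        return int((self.entries["rejected_by"] != "").sum())


def _first_peak_and_later_max(x: np.ndarray) -> tuple[float, float]:
    """Amplitude of the first prominent local maximum (systolic candidate)
    and the largest local maximum after it, measured from the beat minimum."""
    span = float(np.ptp(x))
    peaks, _ = sps.find_peaks(x, prominence=0.05 * span if span > 0 else None)
    base = float(np.min(x))
    if peaks.size == 0:
        return float(np.max(x) - base), -np.inf
    sys_amp = float(x[peaks[0]] - base)
    later = x[peaks[1:]] - base if peaks.size > 1 else np.array([])
    dia_amp = float(np.max(later)) if later.size else -np.inf
    return sys_amp, dia_amp


def reject_abnormal(
    beats: list[BeatSegment],
    max_deviation: float = 0.25,
) -> tuple[list[BeatSegment], RejectionLog]:
    """Drop arrhythmic or morphologically abnormal beats.

    A beat is rejected when
      (a) ``interval``: its duration deviates from the recording's median
          beat duration by more than ``max_deviation`` (default 25%), or
      (b) ``amplitude``: its peak-to-peak amplitude deviates from the median
          by more than ``max_deviation``, or
      (c) ``diastolic-dominant``: a local maximum after the first systolic
          peak exceeds that systolic peak (diastolic amplitude greater than
          systolic amplitude).
    The log records one row per input beat with the rule that fired.
    """
    if not beats:
        return [], RejectionLog(
            pd.DataFrame(
                columns=["subject_id", "beat_index", "onset_s", "duration_s", "rejected_by"]
            )
        )
    durations = np.array([b.duration for b in beats])
    amplitudes = np.array([float(np.ptp(b.samples)) for b in beats])
    med_dur = float(np.median(durations))
    med_amp = float(np.median(amplitudes))

    accepted = []
    rows = []
    for b, dur, amp in zip(beats, durations, amplitudes):
        reason = ""
        if med_dur > 0 and abs(dur - med_dur) > max_deviation * med_dur:
            reason = "interval"
        elif med_amp > 0 and abs(amp - med_amp) > max_deviation * med_amp:
            reason = "amplitude"
        else:
            sys_amp, dia_amp = _first_peak_and_later_max(b.samples)
            if dia_amp > sys_amp:
                reason = "diastolic-dominant"
        rows.append(
            {
                "subject_id": b.subject_id,
                "beat_index": b.beat_index,
                "onset_s": b.onset_s,
                "duration_s": dur,
                "rejected_by": reason,
            }
        )
        if not reason:
            accepted.append(b)
    return accepted, RejectionLog(pd.DataFrame(rows))


def resample_normalize(beat: BeatSegment) -> NormalizedBeat:
    """Interpolate a beat onto the canonical 1000-point grid and min-max
    normalize its amplitude to [0, 1].

    The target grid is t_j = j * duration / 1000 (the same k/fs convention
    as the source samples), so a 1000-sample beat maps onto itself.  The
    original duration in seconds is retained on the output.
    """
    x = beat.samples
    if x.size < 4:
        raise ValueError("beat too short to resample (need >= 4 samples)")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("constant beat cannot be min-max normalized (max == min)")
    t_src = np.arange(x.size) / beat.fs
    n = N_BEAT_SAMPLES
    t_dst = np.linspace(0.0, beat.duration * (n - 1) / n, n)
    y = np.interp(t_dst, t_src, x)
    y = (y - np.min(y)) / (np.max(y) - np.min(y))
    return NormalizedBeat(samples=y, duration=beat.duration, source=beat)
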