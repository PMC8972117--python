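"""Morphological feature extraction from decomposed pulses.

Per accepted beat, 26 basic features are computed from the incident wave
(INC), reflected wave (REF), their crossing (the first inflection point,
INF), the reconstructed pulse (RPPG) and the original pulse (OPPG):
peak amplitudes and times, areas, durations, and time-weighted skewness /
kurtosis of each waveform.  52 combined features are formed as fixed
ratios and differences of the basic ones, grouped into spatial (14),
temporal (13) and spatiotemporal (25) sets, for 78 features in total.
Per subject, the element-wise median over accepted beats is reported.

Conventions (applied uniformly):

* Skewness/kurtosis treat the (nonnegative) waveform as an unnormalized
  density over time; kurtosis is non-excess (a Gaussian scores 3).
* The "time period" of a Gaussian component is the width of the interval
  where it exceeds 1% of its peak (6.07 sigma), clipped to the beat window.
* INF area is the area under the reconstructed pulse from the beat onset
  to the inflection time.
* All times are in seconds of the original beat (the stored duration maps
  the normalized grid back to real time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq

from .core import NormalizedBeat
from .decompose import GaussianDecomposition

__all__ = [
    "BASIC_FEATURE_NAMES",
    "COMBINED_FEATURE_NAMES",
    "FEATURE_NAMES",
    "FeatureError",
    "InflectionPoint",
    "waveform_moments",
    "detect_sys_dia",
    "find_inflection",
    "basic_features",
    "combined_features",
    "beat_feature_vector",
    "subject_feature_vector",
]

BASIC_FEATURE_NAMES: tuple[str, ...] = (
    "INC_peak-amp", "INC_area", "INC_peak-time", "INC_time", "INC_skew", "INC_kurt",
    "REF_peak-amp", "REF_area", "REF_peak-time", "REF_time", "REF_skew", "REF_kurt",
    "INF_peak-amp", "INF_peak-time", "INF_area",
    "RPPG_area", "RPPG_skew", "RPPG_kurt",
    "SYS_peak-amp", "SYS_peak-time", "DIA_peak-amp", "DIA_peak-time",
    "OPPG_area", "OPPG_time", "OPPG_skew", "OPPG_kurt",
)

#: (name, operator, left operand, right operand); order frozen:
#: 14 spatial, then 13 temporal, then 25 spatiotemporal
_COMBINED_DEFS: tuple[tuple[str, str, str], ...] = (
    # spatial
    ("INC_peak-amp", "/", "INC_area"),
    ("INC_peak-amp", "/", "REF_peak-amp"),
    ("INC_peak-amp", "/", "REF_area"),
    ("INC_peak-amp", "/", "RPPG_area"),
    ("INC_area", "/", "REF_peak-amp"),
    ("INC_area", "/", "REF_area"),
    ("INC_area", "/", "RPPG_area"),
    ("REF_peak-amp", "/", "REF_area"),
    ("REF_peak-amp", "/", "RPPG_area"),
    ("REF_area", "/", "RPPG_area"),
    ("INC_peak-amp", "-", "REF_peak-amp"),
    ("INC_area", "-", "REF_area"),
    ("SYS_peak-amp", "-", "INC_peak-amp"),
    ("SYS_peak-amp", "-", "REF_peak-amp"),
    # temporal
    ("INC_peak-time", "/", "INC_time"),
    ("INC_peak-time", "/", "REF_peak-time"),
    ("INC_peak-time", "/", "REF_time"),
    ("INC_peak-time", "/", "OPPG_time"),
    ("INC_time", "/", "REF_peak-time"),
    ("INC_time", "/", "REF_time"),
    ("INC_time", "/", "OPPG_time"),
    ("REF_peak-time", "/", "REF_time"),
    ("REF_peak-time", "/", "OPPG_time"),
    ("REF_time", "/", "OPPG_time"),
    ("REF_peak-time", "-", "INC_peak-time"),
    ("OPPG_time", "-", "INC_peak-time"),
    ("OPPG_time", "-", "REF_peak-time"),
    # spatiotemporal
    ("INC_peak-amp", "/", "INC_peak-time"),
    ("INC_peak-amp", "/", "INC_time"),
    ("INC_peak-amp", "/", "REF_peak-time"),
    ("INC_peak-amp", "/", "REF_time"),
    ("INC_peak-amp", "/", "OPPG_time"),
    ("INC_area", "/", "INC_peak-time"),
    ("INC_area", "/", "INC_time"),
    ("INC_area", "/", "REF_peak-time"),
    ("INC_area", "/", "REF_time"),
    ("INC_area", "/", "OPPG_time"),
    ("REF_peak-amp", "/", "INC_peak-time"),
    ("REF_peak-amp", "/", "INC_time"),
    ("REF_peak-amp", "/", "REF_peak-time"),
    ("REF_peak-amp", "/", "REF_time"),
    ("REF_peak-amp", "/", "OPPG_time"),
    ("REF_area", "/", "INC_peak-time"),
    ("REF_area", "/", "INC_time"),
    ("REF_area", "/", "REF_peak-time"),
    ("REF_area", "/", "REF_time"),
    ("REF_area", "/", "OPPG_time"),
    ("RPPG_area", "/", "INC_peak-time"),
    ("RPPG_area", "/", "INC_time"),
    ("RPPG_area", "/", "REF_peak-time"),
    ("RPPG_area", "/", "REF_time"),
    ("RPPG_area", "/", "OPPG_time"),
)

COMBINED_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{a}{op}{b}" for a, op, b in _COMBINED_DEFS
)

#: canonical ordered names of the full 78-element feature vector
FEATURE_NAMES: tuple[str, ...] = BASIC_FEATURE_NAMES + COMBINED_FEATURE_NAMES

assert len(BASIC_FEATURE_NAMES) == 26
assert len(COMBINED_FEATURE_NAMES) == 52
assert len(FEATURE_NAMES) == 78

#: a component's "time period" spans where it exceeds 1% of its peak:
#: full width 2*sqrt(2*ln 100) sigma
_WIDTH_FACTOR = 2.0 * np.sqrt(2.0 * np.log(100.0))


class FeatureError(ValueError):
    """A beat whose features cannot be resolved (dropped with a reason)."""


@dataclass(frozen=True)
class InflectionPoint:
    """First crossing of the incident and reflected component waveforms."""

    time_s: float
    amplitude: float
    area: float


def waveform_moments(t: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Area, skewness and kurtosis of a nonnegative waveform over time.

    The waveform is treated as an unnormalized density of time: area is the
    trapezoidal integral, skewness/kurtosis are the standardized third and
    fourth central moments of that density (kurtosis non-excess).
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < -1e-12):
        raise ValueError("waveform must be nonnegative")
    area = float(np.trapezoid(w, t))
    if area <= 0:
        raise ValueError("all-zero waveform has no moments")
    # trapezoid quadrature weights for the density integrals
    dt = np.diff(t)
    q = np.zeros_like(t)
    q[:-1] += 0.5 * dt
    q[1:] += 0.5 * dt
    wq = w * q
    m0 = wq.sum()
    mean = float((wq * t).sum() / m0)
    c = t - mean
    m2 = float((wq * c**2).sum() / m0)
    if m2 <= 0:
        raise ValueError("degenerate waveform: zero temporal variance")
    m3 = float((wq * c**3).sum() / m0)
    m4 = float((wq * c**4).sum() / m0)
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    return area, skew, kurt


def detect_sys_dia(
    beat: NormalizedBeat, smooth_window_s: float = 0.05
) -> tuple[float, float, float, float]:
    """Locate the systolic and diastolic peaks of the original pulse.

    The systolic peak is the global maximum.  The diastolic peak is the
    most prominent local maximum after it; when the dicrotic notch has
    vanished and no local maximum exists, the point of maximal second
    derivative (on a Savitzky-Golay-smoothed waveform) after the systolic
    peak is used instead.  Returns (SYS_amp, SYS_time, DIA_amp, DIA_time)
    with times in seconds.

    Raises
    ------
    FeatureError
        If no diastolic candidate exists after the systolic peak.
    """
    y = beat.samples
    t = beat.times
    i_sys = int(np.argmax(y))
    sys_amp, sys_time = float(y[i_sys]), float(t[i_sys])

    tail = y[i_sys + 1 :]
    if tail.size < 5:
        raise FeatureError("no samples after systolic peak; diastolic peak missing")
    peaks, props = sps.find_peaks(tail, prominence=1e-4)
    if peaks.size:
        k = peaks[int(np.argmax(props["prominences"]))]
        i_dia = i_sys + 1 + int(k)
        return sys_amp, sys_time, float(y[i_dia]), float(t[i_dia])

    # notch absent: maximal curvature of the smoothed decay
    n = y.size
    dt = beat.duration / n
    win = max(int(round(smooth_window_s / dt)) | 1, 5)
    win = min(win, n - 1 if (n - 1) % 2 == 1 else n - 2)
    d2 = sps.savgol_filter(y, win, polyorder=3, deriv=2, delta=dt)
    lo = i_sys + max(3, n // 100)
    hi = n - max(3, n // 100)
    if hi <= lo:
        raise FeatureError("no room after systolic peak for diastolic inflection")
    i_dia = lo + int(np.argmax(d2[lo:hi]))
    return sys_amp, sys_time, float(y[i_dia]), float(t[i_dia])


def find_inflection(
    decomp: GaussianDecomposition, n_grid: int = 2000
) -> InflectionPoint:
    """First crossing of the incident and reflected waves between their
    centres, solved by bisection to 1e-6 s.

    The inflection amplitude is the common component value at the crossing;
    its area is the trapezoidal area under the reconstructed pulse from the
    beat onset to the crossing time.

    Raises
    ------
    FeatureError
        If the two components do not cross between their centres.
    """
    inc, ref = decomp.incident, decomp.reflected

    def diff(t: float) -> float:
        return float(inc(t) - ref(t))

    a, b = inc.center_s, ref.center_s
    grid = np.linspace(a, b, 256)
    vals = np.array([diff(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise FeatureError("incident and reflected waves do not cross between centres")
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    t_star = float(brentq(diff, lo, hi, xtol=1e-6))
    amp = float(inc(t_star))

    ts = np.linspace(0.0, t_star, n_grid)
    area = float(np.trapezoid(inc(ts) + ref(ts), ts))
    return InflectionPoint(time_s=t_star, amplitude=amp, area=area)


def _component_time_period(center: float, width: float, duration: float) -> float:
    """Width of the interval where the component exceeds 1% of its peak,
    clipped to the beat window [0, duration]."""
    half = 0.5 * _WIDTH_FACTOR * width
    lo = max(0.0, center - half)
    hi = min(duration, center + half)
    return max(hi - lo, 0.0)


def basic_features(beat: NormalizedBeat, decomp: GaussianDecomposition) -> pd.Series:
    """The 26 basic features of one accepted beat, in canonical order.

    Raises
    ------
    FeatureError
        If the inflection point or the diastolic peak cannot be resolved;
        such beats are dropped from aggregation by the caller.
    """
    t = beat.times
    dur = beat.duration
    inc, ref = decomp.incident, decomp.reflected

    w_inc = inc(t)
    w_ref = ref(t)
    w_rppg = w_inc + w_ref

    inc_area, inc_skew, inc_kurt = waveform_moments(t, w_inc)
    ref_area, ref_skew, ref_kurt = waveform_moments(t, w_ref)
    rppg_area, rppg_skew, rppg_kurt = waveform_moments(t, w_rppg)
    oppg_area, oppg_skew, oppg_kurt = waveform_moments(t, beat.samples)

    inf_pt = find_inflection(decomp)
    sys_amp, sys_time, dia_amp, dia_time = detect_sys_dia(beat)

    values = {
        "INC_peak-amp": inc.amplitude,
        "INC_area": inc_area,
        "INC_peak-time": inc.center_s,
        "INC_time": _component_time_period(inc.center_s, inc.width_s, dur),
        "INC_skew": inc_skew,
        "INC_kurt": inc_kurt,
        "REF_peak-amp": ref.amplitude,
        "REF_area": ref_area,
        "REF_peak-time": ref.center_s,
        "REF_time": _component_time_period(ref.center_s, ref.width_s, dur),
        "REF_skew": ref_skew,
        "REF_kurt": ref_kurt,
        "INF_peak-amp": inf_pt.amplitude,
        "INF_peak-time": inf_pt.time_s,
        "INF_area": inf_pt.area,
        "RPPG_area": rppg_area,
        "RPPG_skew": rppg_skew,
        "RPPG_kurt": rppg_kurt,
        "SYS_peak-amp": sys_amp,
        "SYS_peak-time": sys_time,
        "DIA_peak-amp": dia_amp,
        "DIA_peak-time": dia_time,
        "OPPG_area": oppg_area,
        "OPPG_time": dur,
        "OPPG_skew": oppg_skew,
        "OPPG_kurt": oppg_kurt,
    }
    out = pd.Series(values, index=list(BASIC_FEATURE_NAMES), dtype=float)
    if not np.all(np.isfinite(out.to_numpy())):
        raise FeatureError("non-finite basic feature")
    return out


def combined_features(basic: pd.Series) -> pd.Series:
    """The 52 fixed ratios/differences of basic features, in canonical order.

    Raises
    ------
    FeatureError
        On a zero denominator (the beat is dropped, never NaN-propagated).
    """
    values = {}
    for a, op, b in _COMBINED_DEFS:
        x, y = float(basic[a]), float(basic[b])
        if op == "/":
            if y == 0:
                raise FeatureError(f"zero denominator in {a}/{b}")
            values[f"{a}/{b}"] = x / y
        else:
            values[f"{a}-{b}"] = x - y
    out = pd.Series(values, index=list(COMBINED_FEATURE_NAMES), dtype=float)
    if not np.all(np.isfinite(out.to_numpy())):
        raise FeatureError("non-finite combined feature")
    return out


def beat_feature_vector(
    beat: NormalizedBeat, decomp: GaussianDecomposition
) -> pd.Series:
    """Full 78-element feature vector (26 basic then 52 combined) of one beat."""
    basic = basic_features(beat, decomp)
    comb = combined_features(basic)
    return pd.concat([basic, comb]).reindex(list(FEATURE_NAMES))


def subject_feature_vector(per_beat: list[pd.Series]) -> tuple[pd.Series, int]:
    """Element-wise median across a subject's accepted beats.

    Returns (vector, number of contributing beats); raises ``FeatureError``
    when no beat survived (the subject is excluded).
    """
    if not per_beat:
        raise FeatureError("no accepted beats; subject excluded")
    mat = pd.concat(per_beat, axis=1)
    if list(mat.index) != list(FEATURE_NAMES):
        warnings.warn("per-beat vectors reindexed to canonical order", stacklevel=2)
        mat = mat.reindex(list(FEATURE_NAMES))
    return mat.median(axis=1), len(per_beat)
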