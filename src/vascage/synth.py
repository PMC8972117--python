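"""Synthetic PPG cohort generator.

Every simulated beat is the pointwise sum of an incident and a reflected
Gaussian component, which is exactly the waveform model used by the
decomposition stage.  A cohort plants linear age trends in the beat
parameters (by default the reflected-wave amplitude/width shrink and the
reflected wave returns earlier with age, the directions expected from
progressive arterial stiffening) so that downstream feature extraction and
regression can be validated against a known ground truth.

Simulated recordings add the nuisance structure a pulse-oximeter trace
shows: beat-to-beat interval and amplitude jitter, additive white noise,
slow sinusoidal baseline wander below the analysis passband, and (at a
configurable rate) grossly irregular beats that the rejection stage must
catch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RawRecording

__all__ = [
    "BeatParams",
    "SubjectSpec",
    "CohortSpec",
    "SynthRecording",
    "DEFAULT_BEAT",
    "DEFAULT_TRENDS",
    "REFERENCE_AGE",
    "sample_cohort",
    "synth_beat",
    "synth_recording",
    "gaussian_sum",
]

#: sampling rates the simulator will produce, Hz
SUPPORTED_FS = (125.0, 250.0)

#: age (years) at which a cohort's base beat parameters apply
REFERENCE_AGE = 50.0

#: linear age slopes planted by default (units of the parameter per year)
DEFAULT_TRENDS: dict[str, float] = {
    "a_ref": -0.004,      # reflected amplitude falls with age
    "sigma_ref": -0.0003,  # reflected wave narrows -> REF area falls
}

#: between-subject scatter (sd) around the age trend, per parameter
DEFAULT_JITTER_SD: dict[str, float] = {
    "a_inc": 0.04,
    "sigma_inc": 0.004,
    "a_ref": 0.05,
    "sigma_ref": 0.006,
}

#: pulses start at this fraction of the incident peak (systolic foot)
ONSET_LEVEL = 0.006
#: and decay to this absolute amplitude at the next onset (diastolic tail)
TAIL_LEVEL = 0.02


@dataclass(frozen=True)
class BeatParams:
    """Generating parameters of one two-Gaussian beat.

    Amplitudes in normalized units, centers/widths/duration in seconds.
    """

    a_inc: float
    mu_inc: float
    sigma_inc: float
    a_ref: float
    mu_ref: float
    sigma_ref: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.a_inc > self.a_ref > 0):
            raise ValueError(
                f"require a_inc > a_ref > 0, got a_inc={self.a_inc}, a_ref={self.a_ref}"
            )
        if not (0 < self.mu_inc < self.mu_ref < self.duration):
            raise ValueError(
                "require 0 < mu_inc < mu_ref < duration, got "
                f"mu_inc={self.mu_inc}, mu_ref={self.mu_ref}, duration={self.duration}"
            )
        if self.sigma_inc <= 0 or self.sigma_ref <= 0:
            raise ValueError("widths must be positive")

    def scaled(self, time_factor: float = 1.0, amp_factor: float = 1.0) -> "BeatParams":
        """Return a copy with time fields scaled by ``time_factor`` and
        amplitudes by ``amp_factor`` (shape-preserving)."""
        return BeatParams(
            a_inc=self.a_inc * amp_factor,
            mu_inc=self.mu_inc * time_factor,
            sigma_inc=self.sigma_inc * time_factor,
            a_ref=self.a_ref * amp_factor,
            mu_ref=self.mu_ref * time_factor,
            sigma_ref=self.sigma_ref * time_factor,
            duration=self.duration * time_factor,
        )

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: canonical middle-aged beat (reference age 50): steep systolic upstroke
#: from the onset, clear dicrotic notch, and a diastolic tail that decays
#: into the next onset so consecutive beats join at a sharp local minimum
DEFAULT_BEAT = BeatParams(
    a_inc=1.0, mu_inc=0.20, sigma_inc=0.0625,
    a_ref=0.45, mu_ref=0.70, sigma_ref=0.15,
    duration=1.0,
)


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to simulate one subject's recording."""

    subject_id: str
    age: int
    mean_hr: float
    beat_params_base: BeatParams
    noise_sd: float = 0.0
    wander_amp: float = 0.0
    arrhythmia_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if not (0.0 <= self.arrhythmia_rate <= 1.0):
            raise ValueError("arrhythmia_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.wander_amp < 0:
            raise ValueError("noise_sd and wander_amp must be >= 0")
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """An ordered collection of subjects with the trend table that built it."""

    subjects: tuple[SubjectSpec, ...]
    seed: int
    trend_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Subject table: id, age and the generating beat parameters."""
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "age": s.age, "mean_hr": s.mean_hr}
            row.update(s.beat_params_base.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SynthRecording:
    """A simulated recording plus its per-beat ground truth.

    ``beats`` has one row per generated beat with columns: beat_index,
    onset_index, onset_s, abnormal, and the six Gaussian parameters plus
    duration actually used for that beat.
    """

    recording: RawRecording
    beats: pd.DataFrame


def gaussian_sum(t: np.ndarray, a1, m1, s1, a2, m2, s2) -> np.ndarray:
    """Two-Gaussian waveform model evaluated on time grid ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-((t - m1) ** 2) / (2.0 * s1**2)) + a2 * np.exp(
        -((t - m2) ** 2) / (2.0 * s2**2)
    )


def synth_beat(params: BeatParams, fs: float) -> np.ndarray:
    """Sample one beat on the grid t_k = k / fs, k = 0 .. round(duration*fs)-1."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(params.duration * fs))
    if n < 2:
        raise ValueError("beat too short for this sampling rate")
    t = np.arange(n) / fs
    return gaussian_sum(
        t,
        params.a_inc, params.mu_inc, params.sigma_inc,
        params.a_ref, params.mu_ref, params.sigma_ref,
    )


def _trended_params(
    base: BeatParams,
    age: float,
    trends: dict[str, float],
    jitter: dict[str, float],
    rng: np.random.Generator,
) -> BeatParams:
    """Apply linear age trends (about REFERENCE_AGE) plus Gaussian jitter,
    then clip back into the valid parameter region.

    The two centres are anchored by tail conditions rather than jittered
    independently: every pulse starts at ``ONSET_LEVEL`` of its incident
    peak and its diastolic tail decays to ``TAIL_LEVEL`` at the beat end,
    the way real pulses rise from and return to the diastolic baseline.
    Explicit ``mu_inc``/``mu_ref`` trends or jitter, if configured, are
    added on top of the anchored centres.
    """
    p = base.as_dict()
    d_age = age - REFERENCE_AGE
    for name in ("a_inc", "sigma_inc", "a_ref", "sigma_ref"):
        p[name] += trends.get(name, 0.0) * d_age + rng.normal(0.0, jitter.get(name, 0.0))
    dur = p["duration"]
    p["a_inc"] = float(np.clip(p["a_inc"], 0.3, 2.0))
    p["a_ref"] = float(np.clip(p["a_ref"], 0.08, 0.9 * p["a_inc"]))
    p["sigma_inc"] = float(np.clip(p["sigma_inc"], 0.02, 0.12 * dur))
    p["sigma_ref"] = float(np.clip(p["sigma_ref"], 0.05, 0.20 * dur))
    # anchor the centres to the tail conditions
    mu_inc = p["sigma_inc"] * np.sqrt(-2.0 * np.log(ONSET_LEVEL))
    mu_ref = dur - p["sigma_ref"] * np.sqrt(2.0 * np.log(p["a_ref"] / TAIL_LEVEL))
    mu_inc += trends.get("mu_inc", 0.0) * d_age + rng.normal(0.0, jitter.get("mu_inc", 0.0))
    mu_ref += trends.get("mu_ref", 0.0) * d_age + rng.normal(0.0, jitter.get("mu_ref", 0.0))
    # keep the invariants a_inc > a_ref > 0, 0 < mu_inc < mu_ref < duration
    p["mu_inc"] = float(np.clip(mu_inc, 0.05 * dur, 0.40 * dur))
    p["mu_ref"] = float(np.clip(mu_ref, p["mu_inc"] + 0.15 * dur, 0.85 * dur))
    return BeatParams(**p)


def sample_cohort(
    n: int,
    age_range: tuple[float, float] = (20, 80),
    seed: int = 0,
    trend_config: dict[str, float] | None = None,
    base_beat: BeatParams = DEFAULT_BEAT,
    noise_sd: float = 0.01,
    wander_amp: float = 0.05,
    arrhythmia_rate: float = 0.02,
    jitter_sd: dict[str, float] | None = None,
) -> CohortSpec:
    """Draw a cohort of ``n`` subjects with planted age trends.

    Ages are sampled uniformly (integer years) over ``age_range``; each
    subject's beat parameters follow the linear trend table plus
    per-subject Gaussian jitter.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"degenerate age_range {age_range}: need min < max")
    trends = DEFAULT_TRENDS if trend_config is None else dict(trend_config)
    jitter = DEFAULT_JITTER_SD if jitter_sd is None else dict(jitter_sd)
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        age = int(rng.integers(int(lo), int(hi) + 1))
        mean_hr = float(np.clip(rng.normal(70.0, 7.0), 50.0, 95.0))
        params = _trended_params(base_beat, age, trends, jitter, rng)
        subjects.append(
            SubjectSpec(
                subject_id=f"S{i:04d}",
                age=age,
                mean_hr=mean_hr,
                beat_params_base=params,
                noise_sd=noise_sd,
                wander_amp=wander_amp,
                arrhythmia_rate=arrhythmia_rate,
            )
        )
    return CohortSpec(subjects=tuple(subjects), seed=seed, trend_coefficients=trends)


def synth_recording(
    spec: SubjectSpec,
    fs: float = 125.0,
    duration: float = 60.0,
    seed: int = 0,
    allowed_fs: tuple[float, ...] = SUPPORTED_FS,
) -> SynthRecording:
    """Simulate one subject's PPG stream of (up to) ``duration`` seconds.

    Beats are laid down back to back; the k-th beat occupies the half-open
    window starting at its onset sample, whose waveform is exactly
    ``synth_beat`` of that beat's parameters.  Generation stops before a
    beat would overrun the requested duration, so the stream ends on a
    complete beat.

    Inter-beat intervals jitter around 60/mean_hr (3% sd), overall beat
    amplitude jitters by 3% sd, white noise of sd ``spec.noise_sd`` and a
    0.2 Hz sinusoidal baseline wander of amplitude ``spec.wander_amp`` are
    added, and with probability ``spec.arrhythmia_rate`` a beat's interval
    or amplitude is inflated 2.2x (grossly irregular, for the rejection
    stage to catch).
    """
    if float(fs) not in tuple(float(f) for f in allowed_fs):
        raise ValueError(f"unsupported sampling rate {fs}; allowed: {allowed_fs}")
    if duration <= 0:
        raise ValueError("duration must be positive")

    rng = np.random.default_rng(seed)
    wander_phase = rng.uniform(0.0, 2.0 * np.pi)
    base = spec.beat_params_base
    base_ibi = 60.0 / spec.mean_hr

    total_samples = int(round(duration * fs))
    pieces: list[np.ndarray] = []
    rows: list[dict] = []
    cursor = 0
    beat_index = 0
    while True:
        ibi = base_ibi * rng.normal(1.0, 0.03)
        amp = rng.normal(1.0, 0.03)
        abnormal = bool(rng.random() < spec.arrhythmia_rate)
        if abnormal:
            if rng.random() < 0.5:
                ibi *= 2.2  # long pause
            else:
                amp *= 2.2  # amplitude surge
        params = base.scaled(time_factor=ibi / base.duration, amp_factor=amp)
        wave = synth_beat(params, fs)
        if cursor + wave.size > total_samples:
            break
        pieces.append(wave)
        row = {
            "beat_index": beat_index,
            "onset_index": cursor,
            "onset_s": cursor / fs,
            "abnormal": abnormal,
        }
        row.update(params.as_dict())
        rows.append(row)
        cursor += wave.size
        beat_index += 1
    if not pieces:
        raise ValueError(
            "requested duration too short to hold a single beat at this heart rate"
        )
    signal = np.concatenate(pieces)
    t = np.arange(signal.size) / fs
    if spec.wander_amp > 0:
        signal = signal + spec.wander_amp * np.sin(2.0 * np.pi * 0.2 * t + wander_phase)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.size)

    rec = RawRecording(
        samples=signal, fs=float(fs), subject_id=spec.subject_id, age=float(spec.age)
    )
    beats = pd.DataFrame(rows)
    return SynthRecording(recording=rec, beats=beats)
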