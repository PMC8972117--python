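import numpy as np
import pytest

from vascage.core import N_BEAT_SAMPLES, NormalizedBeat
from vascage.synth import BeatParams, gaussian_sum, sample_cohort, synth_recording


@pytest.fixture
def example_params() -> BeatParams:
    """The worked two-Gaussian beat used across the decomposition tests."""
    return BeatParams(
        a_inc=1.0, mu_inc=0.30, sigma_inc=0.10,
        a_ref=0.40, mu_ref=0.60, sigma_ref=0.15,
        duration=1.0,
    )


def beat_on_grid(params: BeatParams, n: int = N_BEAT_SAMPLES) -> NormalizedBeat:
    """Evaluate a two-Gaussian beat directly on the canonical fitting grid
    (no resampling, no amplitude rescaling)."""
    dur = params.duration
    t = np.linspace(0.0, dur * (n - 1) / n, n)
    y = gaussian_sum(
        t,
        params.a_inc, params.mu_inc, params.sigma_inc,
        params.a_ref, params.mu_ref, params.sigma_ref,
    )
    return NormalizedBeat(samples=y, duration=dur)


def random_params(rng: np.random.Generator) -> BeatParams:
    """A random well-separated two-Gaussian beat for oracle tests."""
    dur = rng.uniform(0.7, 1.2)
    a1 = rng.uniform(0.8, 1.2)
    m1 = rng.uniform(0.15, 0.30) * dur
    s1 = rng.uniform(0.06, 0.10) * dur
    a2 = a1 * rng.uniform(0.30, 0.70)
    m2 = m1 + rng.uniform(0.25, 0.45) * dur
    s2 = rng.uniform(0.08, 0.14) * dur
    return BeatParams(a1, m1, s1, a2, m2, s2, dur)


@pytest.fixture
def clean_recording():
    """One noiseless 250 Hz recording with its ground truth."""
    cohort = sample_cohort(1, seed=11, noise_sd=0.0, wander_amp=0.0, arrhythmia_rate=0.0)
    return synth_recording(cohort.subjects[0], fs=250.0, duration=11.0, seed=42)
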