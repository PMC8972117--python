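"""Morphological features: moments, peaks, inflection, 26+52 vectors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vascage.core import NormalizedBeat
from vascage.decompose import decompose
from vascage.features import (
    BASIC_FEATURE_NAMES,
    COMBINED_FEATURE_NAMES,
    FEATURE_NAMES,
    FeatureError,
    basic_features,
    beat_feature_vector,
    combined_features,
    detect_sys_dia,
    find_inflection,
    subject_feature_vector,
    waveform_moments,
)
from vascage.synth import BeatParams, gaussian_sum

from .conftest import beat_on_grid, random_params


class TestWaveformMoments:
    def test_gaussian_is_symmetric_and_mesokurtic(self):
        t = np.linspace(-0.5, 0.5, 4001)  # +-5 sigma for sigma = 0.1
        w = np.exp(-(t**2) / (2 * 0.1**2))
        area, skew, kurt = waveform_moments(t, w)
        assert abs(skew) <= 1e-6
        assert kurt == pytest.approx(3.0, abs=1e-3)
        assert area == pytest.approx(0.1 * np.sqrt(2 * np.pi), rel=1e-4)

    def test_rectangular_pulse_uniform_moments(self):
        # uniform density: area = T, skew 0, kurtosis 9/5
        t = np.linspace(0.0, 0.8, 8001)
        w = np.ones_like(t)
        area, skew, kurt = waveform_moments(t, w)
        assert area == pytest.approx(0.8, rel=1e-9)
        assert abs(skew) <= 1e-9
        assert kurt == pytest.approx(1.8, abs=1e-3)

    def test_late_tail_gives_positive_skew(self):
        t = np.linspace(0.0, 1.0, 2001)
        w = np.exp(-((t - 0.3) ** 2) / (2 * 0.05**2)) + 0.6 * np.exp(
            -((t - 0.7) ** 2) / (2 * 0.15**2)
        )
        _, skew, _ = waveform_moments(t, w)
        assert skew > 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            waveform_moments(np.linspace(0, 1, 100), np.zeros(100))

    def test_matches_quadrature_oracle(self):
        # brute-force quadrature on a dense grid agrees with the
        # trapezoid-weighted implementation
        rng = np.random.default_rng(3)
        t = np.linspace(0.0, 1.0, 20001)
        w = gaussian_sum(t, 1.0, 0.3, 0.08, 0.5, 0.6, 0.12)
        area, skew, kurt = waveform_moments(t, w)
        m0 = np.trapezoid(w, t)
        mean = np.trapezoid(w * t, t) / m0
        m2 = np.trapezoid(w * (t - mean) ** 2, t) / m0
        m3 = np.trapezoid(w * (t - mean) ** 3, t) / m0
        m4 = np.trapezoid(w * (t - mean) ** 4, t) / m0
        assert skew == pytest.approx(m3 / m2**1.5, abs=1e-6)
        assert kurt == pytest.approx(m4 / m2**2, abs=1e-6)


class TestDetectSysDia:
    def test_well_separated_components(self):
        # narrow, well-separated components give a clear dicrotic notch:
        # SYS near the incident centre, DIA near the reflected centre
        p = BeatParams(1.0, 0.25, 0.07, 0.45, 0.62, 0.09, 1.0)
        nb = beat_on_grid(p)
        sys_amp, sys_t, dia_amp, dia_t = detect_sys_dia(nb)
        assert sys_t == pytest.approx(p.mu_inc, abs=0.02)
        assert dia_t == pytest.approx(p.mu_ref, abs=0.05)
        assert dia_t > sys_t
        assert dia_amp < sys_amp

    def test_notchless_decay_uses_curvature(self):
        # single smooth peak with shoulder: diastolic point must still come
        # after the systolic peak
        t = np.linspace(0.0, 0.999, 1000)
        y = np.exp(-((t - 0.25) ** 2) / (2 * 0.12**2)) + 0.25 * np.exp(
            -((t - 0.55) ** 2) / (2 * 0.22**2)
        )
        sys_amp, sys_t, dia_amp, dia_t = detect_sys_dia(NormalizedBeat(y, 1.0))
        assert dia_t > sys_t

    def test_peak_at_end_flagged(self):
        t = np.linspace(0.0, 0.999, 1000)
        with pytest.raises(FeatureError):
            detect_sys_dia(NormalizedBeat(t.copy(), 1.0))  # monotone ramp


class TestFindInflection:
    def test_bisection_matches_grid_oracle(self, example_params):
        d = decompose(beat_on_grid(example_params), seed=0)
        inf = find_inflection(d)
        tt = np.linspace(d.incident.center_s, d.reflected.center_s, 200001)
        grid_t = tt[np.argmin(np.abs(d.incident(tt) - d.reflected(tt)))]
        assert inf.time_s == pytest.approx(grid_t, abs=1e-4)
        assert inf.amplitude == pytest.approx(float(d.incident(inf.time_s)), abs=1e-9)

    def test_symmetric_configuration_crosses_midway(self):
        t = np.linspace(0.0, 0.999, 1000)
        y = gaussian_sum(t, 0.8, 0.4, 0.1, 0.8 - 1e-9, 0.6, 0.1)
        d = decompose(NormalizedBeat(y, 1.0), seed=0)
        inf = find_inflection(d)
        assert inf.time_s == pytest.approx(0.5, abs=5e-3)

    def test_no_crossing_flagged(self, example_params):
        d = decompose(beat_on_grid(example_params), seed=0)
        dominating = type(d)(
            incident=type(d.incident)(1.0, 0.3, 0.4),  # broad, dominates everywhere
            reflected=type(d.reflected)(0.01, 0.6, 0.05),
            recon_corr=1.0, converged=True, residual_rmse=0.0, duration=1.0,
        )
        with pytest.raises(FeatureError):
            find_inflection(dominating)


class TestFeatureVectors:
    def test_cardinality_26_52_78(self, example_params):
        nb = beat_on_grid(example_params)
        d = decompose(nb, seed=0)
        basic = basic_features(nb, d)
        comb = combined_features(basic)
        vec = beat_feature_vector(nb, d)
        assert len(basic) == 26
        assert len(comb) == 52
        assert len(vec) == 78
        assert list(vec.index) == list(FEATURE_NAMES)
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_gaussian_derived_features_match_generating_params(self):
        # clean synthetic beats: features tied to Gaussian parameters agree
        # with closed forms from the generating parameters
        rng = np.random.default_rng(17)
        for k in range(50):
            p = random_params(rng)
            nb = beat_on_grid(p)
            d = decompose(nb, seed=k)
            b = basic_features(nb, d)
            assert b["INC_peak-amp"] == pytest.approx(p.a_inc, rel=1e-3)
            assert b["REF_peak-amp"] == pytest.approx(p.a_ref, rel=1e-3)
            assert b["INC_peak-time"] == pytest.approx(p.mu_inc, rel=1e-3)
            assert b["REF_peak-time"] == pytest.approx(p.mu_ref, rel=1e-3)
            width = 2 * np.sqrt(2 * np.log(100.0)) * p.sigma_inc
            lo, hi = max(0.0, p.mu_inc - width / 2), min(p.duration, p.mu_inc + width / 2)
            assert b["INC_time"] == pytest.approx(hi - lo, rel=2e-3)
            assert b["OPPG_time"] == pytest.approx(p.duration)

    def test_area_additivity(self, example_params):
        nb = beat_on_grid(example_params)
        d = decompose(nb, seed=0)
        b = basic_features(nb, d)
        assert b["RPPG_area"] == pytest.approx(b["INC_area"] + b["REF_area"], abs=1e-9)

    def test_combined_arithmetic(self):
        basic = pd.Series(1.0, index=list(BASIC_FEATURE_NAMES))
        basic["INC_peak-amp"] = 1.0
        basic["REF_peak-amp"] = 0.4
        comb = combined_features(basic)
        assert comb["INC_peak-amp/REF_peak-amp"] == pytest.approx(2.5)
        assert comb["INC_peak-amp-REF_peak-amp"] == pytest.approx(0.6)

    def test_all_ones_identity(self):
        basic = pd.Series(1.0, index=list(BASIC_FEATURE_NAMES))
        comb = combined_features(basic)
        ratios = [n for n in COMBINED_FEATURE_NAMES if "/" in n]
        diffs = [n for n in COMBINED_FEATURE_NAMES if "/" not in n]
        assert (comb[ratios] == 1.0).all()
        assert (comb[diffs] == 0.0).all()

    def test_zero_denominator_drops_beat(self):
        basic = pd.Series(1.0, index=list(BASIC_FEATURE_NAMES))
        basic["OPPG_time"] = 0.0
        with pytest.raises(FeatureError):
            combined_features(basic)

    def test_duration_scaling_covariance(self, example_params):
        # stretching time by c scales every *_time feature by c and leaves
        # pure amplitude features unchanged
        c = 1.3
        nb1 = beat_on_grid(example_params)
        nb2 = beat_on_grid(example_params.scaled(time_factor=c))
        b1 = basic_features(nb1, decompose(nb1, seed=0))
        b2 = basic_features(nb2, decompose(nb2, seed=0))
        for name in ("INC_peak-time", "REF_peak-time", "INC_time", "REF_time",
                     "OPPG_time", "SYS_peak-time", "DIA_peak-time", "INF_peak-time"):
            assert b2[name] == pytest.approx(c * b1[name], rel=1e-2), name
        for name in ("INC_peak-amp", "REF_peak-amp", "SYS_peak-amp", "DIA_peak-amp",
                     "INF_peak-amp"):
            assert b2[name] == pytest.approx(b1[name], rel=1e-2, abs=1e-3), name


class TestSubjectAggregation:
    def _vec(self, value: float) -> pd.Series:
        return pd.Series(value, index=list(FEATURE_NAMES))

    def test_median_of_single_beat_is_identity(self):
        v = self._vec(2.0)
        out, n = subject_feature_vector([v])
        assert n == 1
        pd.testing.assert_series_equal(out, v)

    def test_median_robust_to_outlier(self):
        vecs = [self._vec(1.0), self._vec(1.0), self._vec(1.0), self._vec(99.0)]
        out, n = subject_feature_vector(vecs)
        assert n == 4
        assert (out == 1.0).all()

    def test_no_beats_excludes_subject(self):
        with pytest.raises(FeatureError):
            subject_feature_vector([])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_vector_length_and_finiteness(seed):
    """Any valid random beat yields a finite 78-vector in canonical order."""
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    nb = beat_on_grid(p)
    vec = beat_feature_vector(nb, decompose(nb, seed=seed))
    assert len(vec) == 78
    assert np.all(np.isfinite(vec.to_numpy()))
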