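"""Preprocessing chain: filtering, onset detection, segmentation,
rejection, resampling/normalization."""

import numpy as np
import pytest

from vascage.core import BeatSegment, RawRecording
from vascage.preprocess import (
    bandpass_filter,
    detect_onsets,
    reject_abnormal,
    resample_normalize,
    segment_beats,
)
from vascage.synth import BeatParams, sample_cohort, synth_beat, synth_recording


def _sine(freq: float, fs: float = 250.0, dur: float = 30.0) -> RawRecording:
    t = np.arange(0.0, dur, 1.0 / fs)
    return RawRecording(np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = RawRecording(np.zeros(5000), 250.0)
        np.testing.assert_array_equal(bandpass_filter(rec).samples, 0.0)

    def test_stopband_attenuates_wander_frequency(self):
        # 0.2 Hz (the simulated baseline wander) must drop by >= 20 dB
        y = bandpass_filter(_sine(0.2)).samples
        assert np.max(np.abs(y[1250:-1250])) <= 0.1

    def test_passband_preserves_pulse_frequencies(self):
        y = bandpass_filter(_sine(2.0)).samples
        assert np.max(np.abs(y[1250:-1250])) >= 0.89

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(RawRecording(np.zeros(100), 20.0))

    def test_preserves_length_and_alignment(self):
        # group delay compensated: a 1 Hz sinusoid keeps its phase
        rec = _sine(1.0)
        y = bandpass_filter(rec).samples
        assert y.size == rec.samples.size
        mid = slice(2500, 5000)
        lag = np.argmax(np.correlate(y[mid], rec.samples[mid], "full")) - (2500 - 1)
        assert abs(lag) <= 1


class TestDetectOnsets:
    def test_constant_signal_yields_no_onsets(self):
        rec = RawRecording(np.ones(2500), 250.0)
        with pytest.warns(UserWarning):
            onsets = detect_onsets(rec)
        assert onsets.size == 0

    def test_matches_ground_truth_within_3_samples(self, clean_recording):
        rec, beats = clean_recording.recording, clean_recording.beats
        onsets = detect_onsets(bandpass_filter(rec))
        truth = beats["onset_index"].to_numpy()
        assert onsets.size == truth.size
        for g in truth:
            assert np.min(np.abs(onsets - g)) <= 3

    def test_filtering_does_not_change_onset_count(self, clean_recording):
        rec = clean_recording.recording
        n_raw = detect_onsets(rec).size
        n_filt = detect_onsets(bandpass_filter(rec)).size
        assert n_raw == n_filt

    def test_single_beat_single_onset(self):
        cohort = sample_cohort(1, seed=8, noise_sd=0.0, wander_amp=0.0, arrhythmia_rate=0.0)
        spec = cohort.subjects[0]
        # duration window fits exactly one beat at this heart rate
        one = synth_recording(spec, fs=125.0, duration=1.7 * 60.0 / spec.mean_hr, seed=3)
        assert len(one.beats) == 1
        onsets = detect_onsets(bandpass_filter(one.recording))
        assert onsets.size == 1

    def test_strictly_increasing(self, clean_recording):
        onsets = detect_onsets(bandpass_filter(clean_recording.recording))
        assert np.all(np.diff(onsets) > 0)


class TestSegmentBeats:
    def test_count_is_onsets_minus_one(self, clean_recording):
        rec = clean_recording.recording
        onsets = np.arange(0, rec.samples.size - 250, 250)
        segs = segment_beats(rec, onsets)
        assert len(segs) == onsets.size - 1

    def test_partition_reconstructs_signal(self, clean_recording):
        rec = clean_recording.recording
        onsets = detect_onsets(bandpass_filter(rec))
        segs = segment_beats(rec, onsets)
        glued = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(glued, rec.samples[onsets[0] : onsets[-1]])

    def test_durations_from_onset_spacing(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=750), 250.0)
        segs = segment_beats(rec, np.array([0, 250, 500]))
        assert [s.duration for s in segs] == [1.0, 1.0]

    def test_fewer_than_two_onsets_empty(self, clean_recording):
        assert segment_beats(clean_recording.recording, np.array([5])) == []


class TestRejectAbnormal:
    @staticmethod
    def _beats_from(params_list, fs=250.0):
        out, cursor = [], 0
        for i, p in enumerate(params_list):
            w = synth_beat(p, fs)
            out.append(BeatSegment(w, fs, cursor, beat_index=i))
            cursor += w.size
        return out

    def test_identical_beats_all_accepted(self, example_params):
        beats = self._beats_from([example_params] * 8)
        accepted, log = reject_abnormal(beats)
        assert len(accepted) == 8
        assert log.n_rejected() == 0

    def test_long_interval_rejected(self, example_params):
        long = example_params.scaled(time_factor=2.0)
        beats = self._beats_from([example_params] * 6 + [long])
        accepted, log = reject_abnormal(beats)
        assert len(accepted) == 6
        assert log.entries.iloc[-1]["rejected_by"] == "interval"

    def test_amplitude_surge_rejected(self, example_params):
        big = example_params.scaled(amp_factor=2.0)
        beats = self._beats_from([example_params] * 6 + [big])
        accepted, log = reject_abnormal(beats)
        assert len(accepted) == 6
        assert log.entries.iloc[-1]["rejected_by"] == "amplitude"

    def test_diastolic_dominant_beat_rejected(self):
        # a beat whose late (diastolic) maximum exceeds its first systolic
        # peak, i.e. the reflected wave dominates the incident wave
        t = np.arange(250) / 250.0
        w = 0.5 * np.exp(-((t - 0.2) ** 2) / (2 * 0.05**2)) + 1.0 * np.exp(
            -((t - 0.6) ** 2) / (2 * 0.08**2)
        )
        normal = synth_beat(BeatParams(1.0, 0.2, 0.06, 0.45, 0.6, 0.1, 1.0), 250.0)
        beats = [BeatSegment(normal, 250.0, i * 250, beat_index=i) for i in range(6)]
        beats.append(BeatSegment(w, 250.0, 6 * 250, beat_index=6))
        accepted, log = reject_abnormal(beats)
        assert log.entries.iloc[-1]["rejected_by"] == "diastolic-dominant"
        assert len(accepted) == 6

    def test_simulated_arrhythmia_caught_downstream(self):
        cohort = sample_cohort(1, seed=21, noise_sd=0.0, wander_amp=0.0, arrhythmia_rate=0.3)
        sr = synth_recording(cohort.subjects[0], fs=250.0, duration=25.0, seed=5)
        if not sr.beats["abnormal"].any():
            pytest.skip("no arrhythmic beat drawn at this seed")
        filt = bandpass_filter(sr.recording)
        onsets = detect_onsets(filt)
        accepted, log = reject_abnormal(segment_beats(filt, onsets))
        assert log.n_rejected() >= 1

    def test_empty_input_empty_output(self):
        accepted, log = reject_abnormal([])
        assert accepted == [] and len(log.entries) == 0


class TestResampleNormalize:
    def test_output_attains_zero_and_one(self, example_params):
        seg = BeatSegment(synth_beat(example_params, 250.0), 250.0, 0)
        nb = resample_normalize(seg)
        assert nb.samples.size == 1000
        assert nb.samples.min() == 0.0
        assert nb.samples.max() == 1.0
        assert nb.duration == pytest.approx(seg.duration)

    def test_fixed_point_for_canonical_beat(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 1000)
        x[0], x[500] = 0.0, 1.0
        seg = BeatSegment(x, 1000.0, 0)
        nb = resample_normalize(seg)
        np.testing.assert_allclose(nb.samples, x, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        # linear interpolation is exact on linear input: the resampled ramp
        # has constant increments (apart from the clamped final sample)
        seg = BeatSegment(np.linspace(0.0, 2.0, 500), 500.0, 0)
        nb = resample_normalize(seg)
        d = np.diff(nb.samples[:-1])
        np.testing.assert_allclose(d, d[0], atol=1e-12)
        assert nb.samples[0] == 0.0 and nb.samples[-1] == 1.0

    def test_constant_beat_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            resample_normalize(BeatSegment(np.ones(500), 250.0, 0))
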