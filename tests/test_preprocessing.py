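"""Filtering, normalization, R detection, segmentation and interval codes."""

import numpy as np
import pytest

from becg.preprocessing import (
    Beat,
    IntervalCode,
    NormalizationParams,
    bandpass_filter,
    decode_interval,
    denormalize,
    detect_r_peaks,
    encode_interval,
    normalize_minmax,
    prepare_record,
    segment_beats,
)
from becg.synthetic import (
    BEAT_LEN,
    MorphologyParams,
    RhythmParams,
    ECGRecord,
    generate_record,
)


def _sine_record(freq, fs=360.0, seconds=4.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return ECGRecord(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestBandpass:
    def test_dc_removed(self):
        rec = ECGRecord(samples=np.full(2000, 5.0), fs=360.0)
        out = bandpass_filter(rec)
        assert np.abs(out.samples).max() < 0.05

    def test_passband_10hz_preserved(self):
        # long record: the 0.5 Hz high-pass edge transient lasts ~2 s
        rec = _sine_record(10.0, seconds=30.0)
        out = np.asarray(bandpass_filter(rec).samples)
        mid = slice(3600, -3600)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_170hz_suppressed(self):
        rec = _sine_record(170.0, seconds=10.0)
        out = np.asarray(bandpass_filter(rec).samples)
        assert np.abs(out[720:-720]).max() < 0.10

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(_sine_record(10.0), high=200.0)


class TestNormalize:
    def test_basic_mapping_and_params(self):
        rec = ECGRecord(samples=np.array([2.0, 4.0, 6.0]), fs=360.0)
        out, params = normalize_minmax(rec)
        np.testing.assert_allclose(out.samples, [0.0, 0.5, 1.0])
        assert (params.min_value, params.max_value) == (2.0, 6.0)

    def test_already_normalized_unchanged(self):
        rec = ECGRecord(samples=np.array([0.0, 1.0]), fs=360.0)
        out, params = normalize_minmax(rec)
        np.testing.assert_allclose(out.samples, [0.0, 1.0])
        assert (params.min_value, params.max_value) == (0.0, 1.0)

    def test_round_trip_exact(self, rng):
        x = rng.normal(size=500) * 37.0 + 11.0
        rec = ECGRecord(samples=x, fs=360.0)
        out, params = normalize_minmax(rec)
        np.testing.assert_allclose(denormalize(out.samples, params), x, rtol=1e-12)
        # order preserved
        assert np.array_equal(np.argsort(out.samples), np.argsort(x))

    def test_constant_record_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_minmax(ECGRecord(samples=np.ones(10), fs=360.0))


class TestDetectRPeaks:
    def test_all_zero_record_empty(self):
        rec = ECGRecord(samples=np.zeros(3000), fs=360.0)
        assert detect_r_peaks(rec).size == 0

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(ECGRecord(samples=np.zeros(500), fs=360.0))

    def test_output_strictly_increasing_with_refractory(self):
        rec = generate_record(MorphologyParams(), RhythmParams(n_beats=30), seed=2)
        peaks = detect_r_peaks(bandpass_filter(rec))
        assert np.all(np.diff(peaks) >= 72)
        assert peaks.min() >= 0 and peaks.max() < len(rec)

    def test_noisy_record_sensitivity(self):
        # noise at 5% of the unit QRS amplitude
        rhythm = RhythmParams(n_beats=100, noise_sd=0.05, baseline_amp=0.08)
        rec = generate_record(MorphologyParams(), rhythm, seed=17)
        peaks = detect_r_peaks(bandpass_filter(rec))
        hits = sum(np.abs(peaks - r).min() <= 5 for r in rec.r_truth)
        assert hits / len(rec.r_truth) >= 0.99


class TestSegmentation:
    def test_window_equals_whole_record_at_r_127(self):
        x = np.arange(BEAT_LEN, dtype=float)
        rec = ECGRecord(samples=x, fs=360.0)
        beats = segment_beats(rec, [127])
        assert len(beats) == 1
        np.testing.assert_array_equal(beats[0].samples, x)

    def test_window_arithmetic(self):
        x = np.arange(1000, dtype=float)
        beats = segment_beats(ECGRecord(samples=x, fs=360.0), [500])
        np.testing.assert_array_equal(beats[0].samples, np.arange(373, 693))

    def test_boundary_beats_skipped(self):
        x = np.arange(1000, dtype=float)
        beats = segment_beats(ECGRecord(samples=x, fs=360.0), [100, 500, 900])
        assert [b.r_index for b in beats] == [500]

    def test_beat_length_enforced(self):
        with pytest.raises(ValueError, match="320"):
            Beat(samples=np.zeros(100), r_index=0)


class TestIntervalCode:
    @pytest.mark.parametrize(
        "rr,flag,mag", [(320, 0, 0), (400, 0, 80), (286, 1, 34), (831, 0, 511)]
    )
    def test_encode_examples(self, rr, flag, mag):
        code = encode_interval(rr)
        assert (code.flag, code.magnitude) == (flag, mag)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="9-bit"):
            encode_interval(832)
        with pytest.raises(ValueError, match="9-bit"):
            encode_interval(-192)

    def test_decode_examples(self):
        assert decode_interval(IntervalCode(0, 0)) == 0
        assert decode_interval(IntervalCode(1, 34)) == -34

    def test_round_trip_all_encodable_gaps(self):
        for rr in range(BEAT_LEN - 511, BEAT_LEN + 512):
            assert decode_interval(encode_interval(rr)) + BEAT_LEN == rr

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            IntervalCode(2, 0)
        with pytest.raises(ValueError):
            IntervalCode(0, 512)


class TestPrepareRecord:
    def test_beats_normalized_and_intervals_consistent(self):
        rec = generate_record(MorphologyParams(), RhythmParams(n_beats=12), seed=9)
        prep = prepare_record(rec, use_truth_peaks=True)
        assert prep.beats.shape[1] == BEAT_LEN
        assert prep.beats.min() >= 0.0 and prep.beats.max() <= 1.0
        assert (prep.intervals[0].flag, prep.intervals[0].magnitude) == (0, 0)
        rr = np.diff(prep.r_indices)
        decoded = np.array([decode_interval(c) for c in prep.intervals[1:]])
        np.testing.assert_array_equal(decoded + BEAT_LEN, rr)
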