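"""Preprocessing: segmentation, constrained beat detection, wavelet
denoising, and normalization, checked against the generator's ground truth."""

import numpy as np
import pytest
from scipy.signal import argrelmax, periodogram

from mstbp.preprocess import (
    BeatSet,
    build_segments,
    detect_abp_beats,
    dwt_denoise,
    extract_labels,
    layer_normalize,
    segment_record,
    soft_threshold,
)
from mstbp.records import Record
from mstbp.synthetic import PhysioParams, generate_record, inject_artifacts


def _band_power(x, fs, lo, hi):
    f, p = periodogram(x, fs)
    return p[(f >= lo) & (f <= hi)].sum()


class TestSegmentRecord:
    @pytest.mark.parametrize(
        "seconds,expected", [(80.0, 10), (7.9, 0), (8.5, 1), (8.0, 1)]
    )
    def test_window_counts(self, seconds, expected):
        n = int(seconds * 125)
        rec = Record(np.zeros(n), np.zeros(n), np.full(n, 100.0))
        segs = segment_record(rec)
        assert len(segs) == expected
        for s in segs:
            assert len(s) == 1000

    def test_channels_cut_synchronously(self, long_record):
        record, _ = long_record
        segs = segment_record(record)
        np.testing.assert_array_equal(segs[2].abp, record.abp[2000:3000])
        np.testing.assert_array_equal(segs[2].ecg, record.ecg[2000:3000])


class TestDetectAbpBeats:
    def test_clean_record_matches_annotations(self, clean_record):
        record, ann = clean_record
        beats = detect_abp_beats(record.abp, record.fs)
        np.testing.assert_array_equal(beats.peak_indices, ann.peak_indices)
        np.testing.assert_array_equal(beats.trough_indices, ann.trough_indices)
        assert beats.n_beats == 10 and len(beats.trough_indices) == 9

    def test_dicrotic_false_peaks_suppressed(self, clean_record):
        record, ann = clean_record
        corrupted = inject_artifacts(record, false_peak_boost=0.2, annotations=ann)
        assert len(argrelmax(corrupted.abp)[0]) == 20  # naive count doubles
        beats = detect_abp_beats(corrupted.abp, corrupted.fs)
        np.testing.assert_array_equal(beats.peak_indices, ann.peak_indices)

    def test_out_of_range_peak_excluded(self):
        sbp = np.full(10, 120.0)
        sbp[4] = 190.0
        record, ann = generate_record(
            PhysioParams(duration=8.0, heart_rate=75.0, sbp_series=sbp)
        )
        beats = detect_abp_beats(record.abp, record.fs)
        assert beats.n_beats == 9
        assert set(beats.peak_indices) == set(ann.peak_indices[sbp <= 180.0])

    def test_out_of_range_trough_drops_beat(self):
        dbp = np.full(10, 80.0)
        dbp[5] = 50.0  # below the 60 mmHg diastolic floor
        record, _ = generate_record(
            PhysioParams(duration=8.0, heart_rate=75.0, dbp_series=dbp)
        )
        beats = detect_abp_beats(record.abp, record.fs)
        assert beats.n_beats < 10
        assert np.all(beats.trough_values >= 60.0)

    def test_peak_spacing_invariant(self, clean_record):
        record, ann = clean_record
        corrupted = inject_artifacts(record, false_peak_boost=0.25, annotations=ann)
        beats = detect_abp_beats(corrupted.abp, corrupted.fs)
        assert np.all(np.diff(beats.peak_indices) > 0.6 * record.fs)

    def test_flat_signal_empty(self):
        beats = detect_abp_beats(np.full(1000, 100.0), 125.0)
        assert beats.is_empty


class TestExtractLabels:
    def test_single_beat(self):
        beats = BeatSet([100], [150], [120.0], [60.0])
        labels = extract_labels(beats)
        assert (labels.sbp, labels.dbp, labels.map) == (120.0, 60.0, 80.0)

    def test_mean_aggregation(self):
        beats = BeatSet([0, 100], [50, 150], [110.0, 130.0], [70.0, 90.0])
        labels = extract_labels(beats)
        assert labels.sbp == 120.0 and labels.dbp == 80.0
        assert labels.map == pytest.approx((120.0 + 2 * 80.0) / 3.0, abs=1e-12)

    def test_median_option(self):
        beats = BeatSet([0, 100, 200], [50, 150, 250], [100.0, 110.0, 160.0], [60.0, 70.0, 100.0])
        labels = extract_labels(beats, aggregate="median")
        assert labels.sbp == 110.0 and labels.dbp == 70.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_labels(BeatSet([], [], [], []))


class TestSoftThreshold:
    def test_definition(self):
        np.testing.assert_array_equal(
            soft_threshold(np.array([3.0, -3.0, 0.5, -0.5]), 1.0),
            [2.0, -2.0, 0.0, 0.0],
        )

    def test_zero_threshold_is_identity(self):
        x = np.random.default_rng(0).normal(size=50)
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


class TestDwtDenoise:
    fs = 125.0
    t = np.arange(1000) / 125.0

    def test_roundtrip_identity(self):
        sig = np.sin(2 * np.pi * 5 * self.t)
        out = dwt_denoise(sig, 7, threshold=False, zero_bands=False)
        assert np.sqrt(np.mean((out - sig) ** 2)) < 1e-8

    def test_drift_removed_ppg_path(self):
        sig = np.sin(2 * np.pi * 5 * self.t) + 2.0 * np.sin(2 * np.pi * 0.1 * self.t)
        out = dwt_denoise(sig, 8)
        assert _band_power(out, self.fs, 0, 0.25) < 0.1 * _band_power(sig, self.fs, 0, 0.25)

    def test_hf_tone_removed_ecg_path(self):
        sig = np.sin(2 * np.pi * 5 * self.t) + 0.5 * np.sin(2 * np.pi * 40 * self.t)
        out = dwt_denoise(sig, 7)
        assert _band_power(out, self.fs, 39, 41) < 0.1 * _band_power(sig, self.fs, 39, 41)

    def test_in_band_tone_preserved(self):
        sig = np.sin(2 * np.pi * 5 * self.t)
        out = dwt_denoise(sig, 7)
        ratio = _band_power(out, self.fs, 4.5, 5.5) / _band_power(sig, self.fs, 4.5, 5.5)
        assert abs(ratio - 1.0) < 0.05

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="256"):
            dwt_denoise(np.zeros(100), 8)

    def test_length_preserved(self):
        out = dwt_denoise(np.random.default_rng(1).normal(size=1000), 7)
        assert len(out) == 1000


class TestLayerNormalize:
    def test_examples(self):
        np.testing.assert_allclose(layer_normalize(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])
        assert layer_normalize(np.array([-5.0, 0.0, 5.0]))[1] == 0.0

    def test_bounds_exact(self):
        x = np.random.default_rng(2).normal(size=500)
        out = layer_normalize(x)
        assert out.min() == -1.0 and out.max() == 1.0

    def test_idempotent(self):
        x = np.random.default_rng(3).normal(size=200)
        once = layer_normalize(x)
        np.testing.assert_allclose(layer_normalize(once), once, atol=1e-15)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            layer_normalize(np.full(10, 4.0))


class TestBuildSegments:
    def test_clean_record_all_accepted(self, long_record):
        record, _ = long_record
        segs = build_segments(record)
        assert len(segs) == 10
        for s in segs:
            assert s.x.shape == (2, 1000)
            assert s.x.min() == -1.0 and s.x.max() == 1.0
            assert s.labels.sbp == pytest.approx(120.0)
            assert s.labels.dbp == pytest.approx(80.0)
            assert s.labels.map == pytest.approx(93.3333333, abs=1e-4)

    def test_out_of_range_window_rejected(self):
        n = 100
        sbp = np.full(n, 120.0)
        sbp[12] = 190.0  # lands in the second 8-s window
        record, _ = generate_record(
            PhysioParams(duration=80.0, heart_rate=75.0, sbp_series=sbp, dbp_series=np.full(n, 80.0))
        )
        log = []
        segs = build_segments(record, log=log)
        assert len(segs) == 9
        assert any("rejected" in line for line in log)

    def test_flat_record_rejected(self):
        n = 2000
        rec = Record(np.zeros(n), np.zeros(n), np.full(n, 100.0))
        assert build_segments(rec) == []

    def test_min_duration_gate(self, clean_record):
        record, _ = clean_record
        assert build_segments(record, min_duration_s=480.0) == []

    def test_deterministic(self, long_record):
        record, _ = long_record
        a = build_segments(record)
        b = build_segments(record)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.x, sb.x)
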