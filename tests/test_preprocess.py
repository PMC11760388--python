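"""Resampling, filtering, segmentation, z-scoring, QRS detection, bSQI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgcl.ecg_io import ECGRecord, RhythmInterval
from ecgcl.preprocess import (bandpass, compute_bsqi, detect_beats_envelope,
                              detect_qrs, match_beats, preprocess_record,
                              quality_filter, resample_record, segment_record,
                              segment_starts, window_label, zscore)
from ecgcl.synthetic import SyntheticRecordSpec, make_synthetic_dataset, synthesize_record
from oracles import count_windows_ref

FS = 128.0


def _record(x, fs, n_chan=1):
    sig = np.tile(np.asarray(x), (n_chan, 1))
    return ECGRecord(signals=sig, fs=fs, lead_names=[], record_id="t")


class TestResample:
    def test_identity_at_target_rate(self):
        rec = _record(np.random.default_rng(0).standard_normal(256), 128)
        out = resample_record(rec, 128)
        assert np.array_equal(out.signals, rec.signals)

    def test_length_follows_rate_ratio(self):
        rec = _record(np.zeros(2500), 250)
        assert resample_record(rec, 128).n_samples == 1280

    def test_passband_tone_preserved(self):
        fs_in = 360.0
        t = np.arange(int(10 * fs_in)) / fs_in
        rec = _record(np.sin(2 * np.pi * 5 * t), fs_in)
        out = resample_record(rec, 128).signals[0]
        spec = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(len(out), 1 / 128)
        assert abs(freqs[np.argmax(spec)] - 5.0) < 0.05
        mid = out[len(out) // 4 : -len(out) // 4]
        assert abs(mid.max() - 1.0) < 0.01

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resample_record(_record(np.zeros(10), 128), 0)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(int(30 * FS), 3.0)
        assert np.max(np.abs(bandpass(x, FS))) < 1e-3 * 3.0

    def test_passband_tone_rms_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = bandpass(x, FS)
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(out**2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_stopband_tone_attenuated(self):
        fs = 200.0  # 60 Hz must lie below Nyquist to be representable
        t = np.arange(int(30 * fs)) / fs
        out = bandpass(np.sin(2 * np.pi * 60 * t), fs)
        assert np.sqrt(np.mean(out**2)) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), fs=64.0, high=40.0)


class TestSegmentation:
    def test_hundred_second_record_no_overlap(self):
        assert len(segment_starts(int(100 * FS), FS, 30, 0)) == 3
        assert list(segment_starts(int(100 * FS), FS, 30, 0) / FS) == [0, 30, 60]

    def test_hundred_second_record_fifteen_overlap(self):
        starts = segment_starts(int(100 * FS), FS, 30, 15)
        assert list(starts / FS) == [0, 15, 30, 45, 60]

    def test_short_record_discarded(self):
        assert len(segment_starts(int(29 * FS), FS, 30, 0)) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(length_s=st.floats(1, 400), overlap=st.sampled_from([0, 15]))
    def test_count_matches_enumeration_oracle(self, length_s, overlap):
        n = int(round(length_s * FS))
        assert len(segment_starts(n, FS, 30, overlap)) == \
            count_windows_ref(n, FS, 30, overlap)

    def test_majority_duration_labelling(self):
        ivs = [RhythmInterval(0, 1000, "N"), RhythmInterval(1000, 4000, "AFIB")]
        assert window_label(ivs, 0, 1800) == 0      # 800/1800 AF
        assert window_label(ivs, 0, 2000) == 1      # exactly half
        assert window_label(ivs, 500, 1500) == 1    # half AF
        assert window_label(ivs, 2000, 3000) == 1   # fully inside AF

    def test_window_inside_one_interval_matches_binary_map(self):
        for code, lab in (("AFIB", 1), ("AFL", 1), ("N", 0), ("SVTA", 0)):
            ivs = [RhythmInterval(0, 10_000, code)]
            assert window_label(ivs, 100, 2000) == lab

    def test_segment_record_labels_and_lengths(self):
        n = int(90 * FS)
        rec = _record(np.random.default_rng(1).standard_normal(n), FS)
        ivs = [RhythmInterval(0, n // 2, "N"), RhythmInterval(n // 2, n, "AFIB")]
        segs = segment_record(rec, ivs, 30, 0)
        assert [s.label for s in segs] == [0, 1, 1]
        assert all(len(s.x) == int(30 * FS) for s in segs)


class TestZscore:
    def test_reference_example(self):
        np.testing.assert_allclose(zscore(np.array([1.0, 2, 3])),
                                   [-1.2247, 0, 1.2247], atol=1e-4)

    def test_constant_guard_flags(self):
        z, flag = zscore(np.array([5.0, 5, 5]), with_flag=True)
        assert np.array_equal(z, np.zeros(3)) and flag

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_standardised(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        z = zscore(x)
        assert abs(z.mean()) < 1e-6 and abs(z.std() - 1) < 1e-6


class TestDetectQrs:
    def test_clean_synthetic_beats_found_within_40ms(self):
        hits = total = 0
        for seed in range(5):
            for cls in ("AF", "non-AF"):
                rec = synthesize_record(
                    SyntheticRecordSpec(rhythm_class=cls, noise_sd=0.0, seed=seed))
                det = detect_qrs(rec.signals[0], rec.fs)
                tol = round(0.04 * rec.fs)
                total += len(rec.r_peaks)
                hits += sum(np.abs(det - r).min() <= tol for r in rec.r_peaks)
        assert hits / total >= 0.99

    def test_all_zero_signal_empty(self):
        assert len(detect_qrs(np.zeros(int(30 * FS)), FS)) == 0

    def test_amplitude_scale_invariance(self, clean_normal_record):
        x = clean_normal_record.signals[0]
        assert np.array_equal(detect_qrs(x, FS), detect_qrs(2 * x, FS))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_qrs(np.zeros(int(FS)), FS)

    def test_detections_strictly_increasing(self, clean_af_record):
        det = detect_qrs(clean_af_record.signals[0], FS)
        assert np.all(np.diff(det) > 0)


class TestBsqi:
    def test_identical_beat_sets_give_one(self, clean_normal_record):
        q = compute_bsqi(clean_normal_record.signals[0], FS)
        assert q.bsqi == 1.0 and q.n_matched == q.n_beats_detector_a

    def test_matcher_oracle_examples(self):
        tol = 0.150 * FS  # 19.2 samples
        # |520-500| = 20 samples = 156 ms: outside the window
        assert match_beats([100, 500, 900], [110, 520, 1300], tol) == 1
        assert match_beats([100, 500, 900], [110, 515, 1300], tol) == 2
        m = match_beats([100, 500, 900], [110, 515, 1300], tol)
        assert m / (3 + 3 - m) == 0.5

    def test_matching_is_one_to_one(self):
        # two detections near one reference beat: only one can match
        assert match_beats([100], [95, 105], 0.150 * FS) == 1
        assert match_beats([95, 105], [100], 0.150 * FS) == 1

    def test_flat_segment_degenerate(self):
        q = compute_bsqi(np.zeros(int(30 * FS)), FS)
        assert q.bsqi == 0.0 and q.degenerate

    def test_quality_filter_strict_threshold(self):
        lab, _ = make_synthetic_dataset(8, 0, seed=2, noise_sd=0.02)
        kept, bsqi = quality_filter(lab, threshold=0.8)
        assert len(kept) == (bsqi >= 0.8).sum()

    def test_clean_segments_all_survive(self):
        lab, _ = make_synthetic_dataset(30, 0, seed=3, noise_sd=0.05)
        kept, _ = quality_filter(lab)
        assert len(kept) == 30

    def test_heavily_corrupted_segments_rejected(self):
        lab, _ = make_synthetic_dataset(16, 0, seed=4, noise_sd=0.02)
        rng = np.random.default_rng(0)
        segs = lab.segments.copy()
        for i in range(len(segs)):
            idx = rng.choice(segs.shape[1], size=segs.shape[1] // 2, replace=False)
            segs[i, idx] = rng.normal(0, 2, size=len(idx))
        lab.segments = segs
        kept, _ = quality_filter(lab)
        assert len(kept) < 0.5 * 16


class TestPipeline:
    def test_full_pipeline_deterministic_and_ordered(self):
        rng = np.random.default_rng(6)
        rec_syn = synthesize_record(
            SyntheticRecordSpec(rhythm_class="non-AF", duration_s=95, seed=6))
        # pretend it was recorded at 200 Hz: upsample so the pipeline resamples
        from scipy.signal import resample_poly
        sig200 = resample_poly(rec_syn.signals, 200, 128, axis=1)
        rec = ECGRecord(signals=sig200, fs=200.0, lead_names=["I", "II"],
                        record_id="syn")
        ivs = [RhythmInterval(0, sig200.shape[1], "N")]
        a = preprocess_record(rec, ivs, analysis_channel=1, paired_channel=0)
        b = preprocess_record(rec, ivs, analysis_channel=1, paired_channel=0)
        assert np.array_equal(a.segments, b.segments)
        assert len(a) == 3  # floor((95-30)/30)+1
        assert np.allclose(a.segments.mean(axis=1), 0, atol=1e-5)
        assert (a.labels == 0).all()
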