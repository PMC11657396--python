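"""RR-interval segmentation, HRV features and the synthetic rhythm generator."""

import numpy as np
import pytest

from gammafs import GammaEvaluator, LabeledDataset
from gammafs.hrv import (FEATURE_NAMES, RRSeries, hrv_features,
                         patient_level_split, segment_rr, synth_rr)


class TestSegmentRR:
    def test_regular_beats_two_windows(self):
        segs = segment_rr(RRSeries(np.ones(120)), 60.0)
        assert len(segs) == 2
        assert all(s.intervals.size == 60 for s in segs)

    def test_partial_window_dropped(self):
        assert segment_rr(RRSeries(np.full(59, 1.0)), 60.0) == []

    def test_cumulative_time_assignment(self):
        segs = segment_rr(RRSeries(np.full(200, 0.75)), 60.0)
        assert len(segs) == 2                      # 150 s total
        assert all(s.intervals.size == 80 for s in segs)

    def test_empty_series(self):
        assert segment_rr(RRSeries(np.array([]))) == []

    def test_positive_intervals_enforced(self):
        with pytest.raises(ValueError):
            RRSeries(np.array([1.0, -0.5]))


class TestHrvFeatures:
    def test_constant_series_all_variability_zero(self):
        f = hrv_features(RRSeries(np.ones(90)))
        for name in ("SDNN", "SDSD", "RMSSD", "pNN50", "MADRR", "IRRR",
                     "sd.0df", "sd.1df", "sd.2df", "mn.1df", "mn.2df", "TINN",
                     "SDANN", "SDNNIDX"):
            assert f[name] == pytest.approx(0.0), name
        assert f["mn.0df"] == pytest.approx(1.0)
        assert set(f) == set(FEATURE_NAMES)

    def test_alternating_beats(self):
        iv = np.tile([0.8, 1.2], 40)
        f = hrv_features(RRSeries(iv))
        assert f["pNN50"] == pytest.approx(100.0)
        assert f["MADRR"] == pytest.approx(400.0)

    def test_hand_computed_rmssd(self):
        f = hrv_features(RRSeries(np.array([1.0, 1.1, 0.9, 1.0])))
        # diffs 100, -200, 100 ms -> rms = sqrt(60000/3) = 141.42
        assert f["RMSSD"] == pytest.approx(141.42, abs=0.01)
        assert f["pNN50"] == pytest.approx(100.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            hrv_features(RRSeries(np.array([1.0, 1.0])))

    def test_subwindow_features_undefined_when_too_short(self):
        f = hrv_features(RRSeries(np.full(9, 1.0)))   # 9 s: one 5-s window
        assert np.isnan(f["SDANN"]) and np.isnan(f["SDNNIDX"])

    def test_pure_function_of_segment(self):
        seg = synth_rr("AF", 300, 5)
        assert hrv_features(seg) == hrv_features(RRSeries(seg.intervals.copy()))

    def test_nonnegative_dispersion_features(self):
        for seed in range(3):
            for rhythm in ("AF", "NSR"):
                f = hrv_features(segment_rr(synth_rr(rhythm, 180, seed))[0])
                assert f["SDNN"] >= 0 and f["RMSSD"] >= 0 and f["TINN"] >= 0
                assert 0 <= f["pNN50"] <= 100


class TestSynthRR:
    def test_seed_determinism(self):
        a, b = synth_rr("NSR", 200, 9), synth_rr("NSR", 200, 9)
        assert np.array_equal(a.intervals, b.intervals)

    def test_duration_and_validation(self):
        s = synth_rr("AF", 600, 0)
        assert s.duration >= 600
        with pytest.raises(ValueError):
            synth_rr("AF", 30, 0)
        with pytest.raises(ValueError):
            synth_rr("VT", 300, 0)

    def test_nsr_mean_interval_in_physiological_band(self):
        segs = segment_rr(synth_rr("NSR", 3600, 21))
        means = [hrv_features(s)["mn.0df"] for s in segs]
        frac = np.mean([(0.75 <= m <= 1.0) for m in means])
        assert frac >= 0.9

    def test_af_more_irregular_than_nsr(self):
        af = [hrv_features(s) for s in segment_rr(synth_rr("AF", 1200, 3))]
        nsr = [hrv_features(s) for s in segment_rr(synth_rr("NSR", 1200, 3))]
        assert np.mean([f["pNN50"] for f in af]) > np.mean([f["pNN50"] for f in nsr])
        assert np.mean([f["SDNN"] for f in af]) > np.mean([f["SDNN"] for f in nsr])

    def test_generator_hits_dispersion_targets(self):
        af_sdnn = np.mean([hrv_features(s)["SDNN"]
                           for s in segment_rr(synth_rr("AF", 3600, 8))])
        nsr_sdnn = np.mean([hrv_features(s)["SDNN"]
                            for s in segment_rr(synth_rr("NSR", 3600, 8))])
        assert af_sdnn == pytest.approx(145, abs=30)
        assert nsr_sdnn == pytest.approx(50, abs=20)


class TestPatientLevelSplit:
    def test_two_subjects_one_per_side(self):
        segs = (segment_rr(synth_rr("AF", 300, 1, subject_id="a"))
                + segment_rr(synth_rr("NSR", 300, 2, subject_id="b")))
        train, valid = patient_level_split(segs, 0.5, seed=0)
        assert train and valid
        assert {s.subject_id for s in train}.isdisjoint({s.subject_id for s in valid})

    def test_no_subject_spans_sides_many_subjects(self):
        segs = []
        for i in range(10):
            segs += segment_rr(synth_rr("AF" if i % 3 == 0 else "NSR",
                                        240 + 60 * (i % 4), i, subject_id=f"p{i}"))
        train, valid = patient_level_split(segs, 0.6, seed=4)
        assert {s.subject_id for s in train}.isdisjoint({s.subject_id for s in valid})
        assert len(train) + len(valid) == len(segs)

    def test_train_share_near_fraction(self):
        segs = []
        for i in range(34):
            segs += segment_rr(synth_rr("AF" if i < 11 else "NSR",
                                        180 + 30 * (i % 5), 100 + i,
                                        subject_id=f"s{i:02d}"))
        shares = []
        for seed in range(20):
            train, valid = patient_level_split(segs, 0.6, seed=seed)
            shares.append(len(train) / len(segs))
        assert all(0.5 <= s <= 0.75 for s in shares)


def test_af_nsr_separable_by_sdnn_index_gamma():
    """On >=1000 synthetic segments the SDNNIDX feature alone separates
    the rhythm-class ellipsoids (positive gamma)."""
    feats, labels = [], []
    for i in range(9):
        for rhythm, code in (("AF", 2), ("NSR", 1)):
            series = synth_rr(rhythm, 3900, 500 + 10 * i + code)
            for seg in segment_rr(series):
                feats.append(hrv_features(seg)["SDNNIDX"])
                labels.append(code)
    assert len(feats) >= 1000
    data = LabeledDataset(np.array(feats)[:, None], np.array(labels))
    assert GammaEvaluator(data)([0]) > 0
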