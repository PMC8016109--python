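import numpy as np
import pandas as pd
import pytest

from statekit import sleep as slp, synth
from statekit.core_io import EpochSet, TimeSeries


def make_epochs(features, labels=None):
    df = pd.DataFrame(features)
    epochs = [(15.0 * i, 15.0 * i + 30.0) for i in range(len(df))]
    return EpochSet(epochs, df, labels)


@pytest.fixture(scope="module")
def signals():
    fs = 1000.0
    t = np.arange(0, 90, 1 / fs)
    lfp = TimeSeries(np.sin(2 * np.pi * 2.0 * t), fs=fs)
    emg = TimeSeries(0.5 * np.random.default_rng(0).standard_normal(t.size),
                     fs=fs)
    movement = np.zeros(t.size, dtype=bool)
    return lfp, emg, movement


class TestEpochFeatures:
    def test_90s_recording_gives_5_epochs(self, signals):
        es = slp.epoch_features(*signals)
        assert len(es) == 5
        assert es.epochs[-1] == (60.0, 90.0)

    def test_pure_delta_dominates_theta(self, signals):
        es = slp.epoch_features(*signals)
        assert (es.features["delta"] > 10 * es.features["theta"]).all()

    def test_emg_power_scales_quadratically(self, signals):
        lfp, emg, movement = signals
        es1 = slp.epoch_features(lfp, emg, movement)
        emg2 = TimeSeries(2 * emg.samples, fs=emg.fs)
        es2 = slp.epoch_features(lfp, emg2, movement)
        assert np.allclose(es2.features["emg"], 4 * es1.features["emg"],
                           rtol=1e-9)

    def test_misaligned_lengths_rejected(self, signals):
        lfp, emg, _ = signals
        with pytest.raises(ValueError):
            slp.epoch_features(lfp, emg, np.zeros(10, dtype=bool))


class TestRuleClassify:
    def test_movement_forces_wake(self):
        feats = {"delta": [10.0, 1.0, 1.0, 1.0, 1.0],
                 "theta": [1.0] * 5,
                 "ratio": [0.1, 1.0, 1.0, 1.0, 1.0],
                 "emg": [0.1, 1.0, 2.0, 3.0, 4.0],
                 "movement": [True, False, False, False, False]}
        es = slp.rule_classify(make_epochs(feats))
        assert es.labels[0] == "wake"

    def test_nrem_rule_as_stated(self):
        # epoch 0: delta above the 70th pct, EMG below median, no movement,
        # ratio at/below its 70th pct -> NREM
        feats = {"delta": [10.0, 1.0, 1.0, 2.0, 1.5, 1.2, 1.1, 1.3, 1.4, 1.6],
                 "theta": [1.0] * 10,
                 "emg": [0.5, 3.0, 4.0, 5.0, 2.0, 6.0, 7.0, 8.0, 2.5, 3.5],
                 "movement": [False] * 10}
        feats["ratio"] = [t / d for t, d in zip(feats["theta"], feats["delta"])]
        es = slp.rule_classify(make_epochs(feats))
        assert es.labels[0] == "NREM"

    def test_no_rule_matched_uncertain(self):
        feats = {"delta": [1.0, 1.1, 1.2, 0.9, 1.0],
                 "theta": [1.0, 1.1, 1.2, 0.9, 1.0],
                 "ratio": [1.0] * 5,
                 "emg": [1.0, 1.1, 1.2, 0.9, 1.05],
                 "movement": [False] * 5}
        es = slp.rule_classify(make_epochs(feats))
        assert "uncertain" in es.labels

    def test_deterministic_and_scale_invariant(self):
        es, _ = synth.gen_epoch_features(200, seed=3)
        a = slp.rule_classify(es).labels
        b = slp.rule_classify(es).labels
        assert a == b
        scaled = es.features.copy()
        scaled["emg"] = scaled["emg"] * 7.5
        c = slp.rule_classify(EpochSet(list(es.epochs), scaled)).labels
        assert a == c

    def test_idempotent(self):
        es, _ = synth.gen_epoch_features(100, seed=4)
        once = slp.rule_classify(es)
        twice = slp.rule_classify(once)
        assert once.labels == twice.labels


class TestKnnExtend:
    def test_never_relabels_ruled_epochs(self):
        es, _ = synth.gen_epoch_features(300, seed=5, separability=2.0)
        ruled = slp.rule_classify(es)
        ext = slp.knn_extend(ruled)
        for r, e in zip(ruled.labels, ext.labels):
            if r != "uncertain":
                assert e == r

    def test_separable_features_high_accuracy(self):
        es, gt = synth.gen_epoch_features(400, seed=6, separability=8.0)
        ruled = slp.rule_classify(es)
        ext = slp.knn_extend(ruled)
        truth = np.array(gt.epoch_labels)
        pred = np.array(ext.labels)
        unc_before = np.mean(np.array(ruled.labels) == "uncertain")
        unc_after = np.mean(pred == "uncertain")
        assert unc_after < unc_before
        lab = pred != "uncertain"
        assert (pred[lab] == truth[lab]).mean() >= 0.95

    def test_ambiguous_epoch_stays_uncertain(self):
        # one uncertain epoch exactly between two labeled clusters
        n = 50
        # mirror-symmetric clusters (small within-class spread avoids
        # degenerate all-one-class tie-breaking in the neighbor search)
        j = [0.001 * i for i in range(n)]
        feats = {"delta": [0.0 + e for e in j] + [10.0 - e for e in j] + [5.0],
                 "theta": [0.0] * (2 * n + 1),
                 "ratio": [0.0] * (2 * n + 1),
                 "emg": [10.0 - e for e in j] + [0.0 + e for e in j] + [5.0],
                 "movement": [1.0] * n + [0.0] * n + [0.5]}
        labels = ["wake"] * n + ["NREM"] * n + ["uncertain"]
        ext = slp.knn_extend(make_epochs(feats, labels), k=20)
        assert ext.labels[-1] == "uncertain"

    def test_no_labels_error(self):
        es, _ = synth.gen_epoch_features(60, seed=7)
        with pytest.raises(ValueError):
            slp.knn_extend(es)  # all uncertain


class TestCleanPupil:
    def test_clean_series_identity(self):
        p = slp.PupilSeries(np.linspace(4, 6, 100), np.ones(100), fs=10.0)
        out = slp.clean_pupil_series(p)
        assert np.allclose(out.values, p.values)

    def test_low_certainty_sample_interpolated(self):
        vals = np.array([4.0, 0.0, 6.0])
        cert = np.array([1.0, 0.1, 1.0])
        out = slp.clean_pupil_series(slp.PupilSeries(vals, cert, fs=1.0))
        assert out.values[1] == pytest.approx(5.0)

    def test_blink_dips_removed(self, rng):
        fs = 30.0
        n = 3000
        vals = 5.0 + 0.05 * rng.standard_normal(n)
        dips = [200, 1000, 2400]
        for d in dips:
            vals[d:d + 5] = 0.0
        out = slp.clean_pupil_series(
            slp.PupilSeries(vals.copy(), np.ones(n), fs=fs))
        # every dip sample is restored to the local level
        for d in dips:
            assert np.all(out.values[d:d + 5] > 4.0)
        # only below-median samples were touched, and few of them (the
        # 3-MAD rule also trims the lower tail of ordinary noise)
        altered = np.flatnonzero(np.abs(out.values - vals) > 1e-12)
        assert np.all(vals[altered] < np.median(vals))
        assert altered.size < 0.05 * n

    def test_all_uncertain_error(self):
        with pytest.raises(ValueError):
            slp.clean_pupil_series(
                slp.PupilSeries(np.ones(10), np.zeros(10), fs=1.0))


class TestClassifyFromPupil:
    def test_separable_features_near_perfect(self):
        # the quantile transform is rank-based, so even disjoint class
        # supports land on adjacent ranks; boundary k-NN errors bound the
        # attainable accuracy slightly below 1
        es, gt = synth.gen_epoch_features(400, seed=8, separability=8.0,
                                          class_mix=(0.4, 0.35, 0.25))
        res = slp.classify_from_pupil(es.features, gt.epoch_labels, seed=0)
        for c, acc in res["per_class_accuracy"].items():
            assert acc >= 0.95

    def test_rem_overlap_reproduces_rem_deficit(self):
        es, gt = synth.gen_epoch_features(400, seed=9, separability=6.0,
                                          rem_overlap_nrem=True)
        res = slp.classify_from_pupil(es.features, gt.epoch_labels, seed=0)
        acc = res["per_class_accuracy"]
        assert acc["REM"] < 0.5 < acc["NREM"]
        assert acc["wake"] > 0.9

    def test_shuffled_labels_near_chance(self):
        es, gt = synth.gen_epoch_features(300, seed=10, separability=6.0)
        r = np.random.default_rng(0)
        shuffled = list(r.permutation(gt.epoch_labels))
        res = slp.classify_from_pupil(es.features, shuffled, seed=0)
        # overall accuracy should hover near the class-frequency baseline
        cm = res["confusion_matrix"]
        overall = np.trace(cm) / cm.sum()
        freqs = np.bincount(
            pd.Categorical(shuffled, categories=res["classes"]).codes)
        baseline = (freqs / freqs.sum()).max()
        assert overall < baseline + 0.15
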