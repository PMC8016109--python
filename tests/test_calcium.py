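import numpy as np
import pandas as pd
import pytest

from statekit import calcium as ca, synth
from statekit.core_io import TraceMatrix


def make_tm(F, fs=30.0, Fneu=None):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if Fneu is None:
        Fneu = np.zeros_like(F)
    return TraceMatrix(F, Fneu, fs=fs)


class TestPreprocess:
    def test_zero_neuropil_identity(self, rng):
        F = rng.standard_normal((3, 50))
        tm = make_tm(F)
        assert np.allclose(ca.preprocess_traces(tm).F, F)

    def test_equal_neuropil_leaves_30_percent(self, rng):
        F = rng.standard_normal((2, 50))
        tm = TraceMatrix(F, F.copy(), fs=30.0)
        assert np.allclose(ca.preprocess_traces(tm).F, 0.3 * F)

    def test_shared_background_removed(self, calcium_recovery):
        tm, gt = calcium_recovery
        cor = ca.preprocess_traces(tm)
        bg = gt.extra["background"]
        cc = [abs(np.corrcoef(cor.F[i], bg)[0, 1]) for i in range(cor.n_rois)]
        raw = [abs(np.corrcoef(tm.F[i], bg)[0, 1]) for i in range(tm.n_rois)]
        assert np.mean(cc) < 0.05
        assert np.mean(cc) < 0.2 * np.mean(raw)

    def test_dff_excludes_nonpositive_baseline(self):
        F = np.vstack([np.full(100, -5.0), np.full(100, 50.0) + np.arange(100) * 0.1])
        tm = make_tm(F)
        out = ca.preprocess_traces(tm, neuropil_frac=0.0, dff=True)
        assert out.n_rois == 1


class TestDetectTransients:
    def test_flat_trace_none(self):
        det = ca.detect_transients(make_tm(np.zeros((1, 100))))
        assert det.peaks["roi0"].size == 0

    def test_distance_rule_merges_close_peaks(self):
        F = np.zeros((1, 100))
        F[0, 40] = 300.0
        F[0, 45] = 290.0
        det = ca.detect_transients(make_tm(F))
        assert det.peaks["roi0"].size == 1

    def test_generator_count_within_5_percent(self, calcium_recovery):
        tm, gt = calcium_recovery
        det = ca.detect_transients(ca.preprocess_traces(tm))
        true_n = sum(t.size for t in gt.spike_times.values())
        det_n = sum(p.size for p in det.peaks.values())
        assert abs(det_n - true_n) <= 0.05 * true_n

    def test_threshold_sweep_preserves_condition_ranking(self):
        """Rank order of high- vs low-activity populations by transient
        rate is invariant across detection thresholds 50-700 a.u."""
        def pop(rate_scale, seed):
            p = synth.StateParams(rate_scale=rate_scale)
            ss, _ = synth.gen_spikes(p, 10, 120.0, seed=seed, base_rate=0.4)
            tm, _ = synth.gen_calcium(ss, tau=0.7, fs=30.0, seed=seed,
                                      amp=400.0, noise_sd=40.0)
            return ca.preprocess_traces(tm)

        wake, anes = pop(1.0, 11), pop(0.3, 12)
        thresholds = np.array([50, 200, 400, 700], dtype=float)
        sw_w = ca.threshold_sweep(wake, thresholds)
        sw_a = ca.threshold_sweep(anes, thresholds)
        for thr in thresholds:
            nw = sw_w.loc[sw_w.threshold == thr, "n_transients"].sum()
            na = sw_a.loc[sw_a.threshold == thr, "n_transients"].sum()
            assert nw > na


class TestEstimateDecay:
    def test_noiseless_exponential_exact(self):
        fs, tau = 30.0, 0.7
        t = np.arange(0, 3, 1 / fs)
        F = np.zeros((1, 200))
        F[0, 30:30 + t.size] = 400 * np.exp(-t / tau)
        tm = make_tm(F)
        det = ca.detect_transients(tm)
        de = ca.estimate_decay(tm, det)
        assert de.tau["roi0"] == pytest.approx(0.7, abs=0.01)

    def test_slow_decay_excluded_as_failed(self):
        fs = 30.0
        t = np.arange(0, 8, 1 / fs)
        F = np.zeros((1, 300))
        F[0, 30:30 + t.size] = 400 * np.exp(-t / 3.0)
        tm = make_tm(F)
        de = ca.estimate_decay(tm, ca.detect_transients(tm))
        assert "roi0" in de.excluded
        assert np.isnan(de.tau["roi0"])

    def test_snr10_recovery_within_15_percent(self, calcium_recovery):
        tm, gt = calcium_recovery
        cor = ca.preprocess_traces(tm)
        de = ca.estimate_decay(cor, ca.detect_transients(cor))
        taus = [t for t in de.tau.values() if np.isfinite(t)]
        assert len(taus) >= 15
        assert np.median(taus) == pytest.approx(gt.tau, rel=0.15)

    def test_ar1_alternative_close_to_truth(self, calcium_recovery):
        tm, gt = calcium_recovery
        cor = ca.preprocess_traces(tm)
        de = ca.estimate_decay(cor, ca.detect_transients(cor), method="ar1")
        taus = [t for t in de.tau.values() if np.isfinite(t)]
        assert np.median(taus) == pytest.approx(gt.tau, rel=0.3)


class TestActivityMetrics:
    def test_zero_trace(self):
        m = ca.trace_activity_metrics(make_tm(np.zeros((1, 50))))
        assert m.loc[0, "integral"] == 0.0 and m.loc[0, "sd"] == 0.0

    def test_square_pulse_integral(self):
        F = np.zeros((1, 100))
        F[0, 10:40] = 1.0  # 1 s at 30 Hz
        m = ca.trace_activity_metrics(make_tm(F))
        assert m.loc[0, "integral"] == pytest.approx(30.0)

    def test_monotone_in_spike_rate(self):
        vals = []
        for i, scale in enumerate([0.2, 0.5, 1.0, 2.0, 4.0]):
            p = synth.StateParams(rate_scale=scale)
            ss, _ = synth.gen_spikes(p, 8, 60.0, seed=40 + i, base_rate=0.4)
            tm, _ = synth.gen_calcium(ss, tau=0.7, fs=30.0, seed=40 + i,
                                      neuropil_frac=0.0, background_sd=0.0,
                                      noise_sd=20.0)
            vals.append(ca.trace_activity_metrics(tm)["integral"].mean())
        assert np.all(np.diff(vals) > 0)


class TestCorrelations:
    def test_self_copy_clipped_not_infinite(self, rng):
        x = rng.standard_normal(100)
        tm = make_tm(np.vstack([x, x]))
        cm = ca.pairwise_correlations(tm)
        assert np.isfinite(cm.z).all()
        assert cm.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_noise_null(self, rng):
        zs = []
        for _ in range(40):
            tm = make_tm(rng.standard_normal((2, 200)))
            zs.append(ca.pairwise_correlations(tm).z[0, 1])
        zs = np.array(zs)
        se = zs.std(ddof=1) / np.sqrt(zs.size)
        assert abs(zs.mean()) < 3 * se + 1e-3

    def test_coupled_population_larger_mean_abs_z(self):
        def pop(coupling, seed):
            p = synth.StateParams(coupling=coupling)
            ss, _ = synth.gen_spikes(p, 10, 120.0, seed=seed, base_rate=1.0)
            tm, _ = synth.gen_calcium(ss, tau=0.7, fs=30.0, seed=seed,
                                      neuropil_frac=0.0, background_sd=0.0,
                                      noise_sd=20.0)
            cm = ca.pairwise_correlations(tm)
            return np.abs(cm.offdiag()).mean()

        assert pop(0.8, 3) > pop(0.0, 3)

    def test_spearman_monotone_with_pearson_ordering(self, rng):
        tm = make_tm(rng.standard_normal((5, 150)))
        zp = ca.pairwise_correlations(tm, "pearson").offdiag()
        zs = ca.pairwise_correlations(tm, "spearman").offdiag()
        # Fisher transform preserves ordering of raw r
        assert (np.argsort(zp) == np.argsort(np.tanh(zp))).all()
        assert zs.shape == zp.shape

    def test_row_order_invariance(self, rng):
        F = rng.standard_normal((6, 120))
        z1 = ca.pairwise_correlations(make_tm(F)).z
        perm = rng.permutation(6)
        z2 = ca.pairwise_correlations(make_tm(F[perm])).z
        assert np.allclose(z1[np.ix_(perm, perm)], z2)


class TestPopulationCoupling:
    def test_identical_rois_coupling_one(self, rng):
        x = rng.standard_normal(200)
        tm = make_tm(np.vstack([x, x, x, x]))
        pc = ca.population_coupling(tm)
        assert np.allclose(pc["coupling"], 1.0)

    def test_outsider_has_lowest_coupling(self, rng):
        shared = rng.standard_normal(300)
        rows = [shared + 0.3 * rng.standard_normal(300) for _ in range(4)]
        rows.append(rng.standard_normal(300))
        pc = ca.population_coupling(make_tm(np.array(rows)))
        assert pc["coupling"].idxmin() == 4

    def test_shuffled_null(self, rng):
        vals = []
        for _ in range(30):
            tm = make_tm(rng.standard_normal((5, 150)))
            vals.extend(ca.population_coupling(tm)["coupling"])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se + 1e-3


class TestPopulationPower:
    def test_shared_slow_modulation_peak(self):
        # shared 0.15 Hz sinusoidal rate modulation across ROIs
        fs, T = 30.0, 300.0
        t = np.arange(0, T, 1 / fs)
        r = np.random.default_rng(5)
        mod = 1 + 0.9 * np.sin(2 * np.pi * 0.15 * t)
        F = np.array([200 * mod + 30 * r.standard_normal(t.size)
                      for _ in range(15)])
        ps = ca.population_power(make_tm(F))
        sel = ps.freqs > 0.05
        fpeak = ps.freqs[sel][np.argmax(ps.power[sel])]
        assert 0.1 <= fpeak <= 0.2

    def test_independent_rois_no_dominant_peak(self, rng):
        F = rng.standard_normal((15, 9000))
        ps = ca.population_power(make_tm(F))
        sel = ps.freqs > 0.05
        assert ps.power[sel].max() < 3 * np.median(ps.power[sel])

    def test_duplicating_rois_keeps_peak_frequency(self):
        fs, T = 30.0, 120.0
        t = np.arange(0, T, 1 / fs)
        x = np.sin(2 * np.pi * 0.15 * t)
        r = np.random.default_rng(1)
        base = [x + 0.5 * r.standard_normal(t.size) for _ in range(5)]
        ps1 = ca.population_power(make_tm(np.array(base)))
        ps2 = ca.population_power(make_tm(np.array(base + base)))
        sel = ps1.freqs > 0.05
        f1 = ps1.freqs[sel][np.argmax(ps1.power[sel])]
        f2 = ps2.freqs[sel][np.argmax(ps2.power[sel])]
        assert f1 == f2


class TestRecoveryNormalization:
    def make_metrics(self, rates):
        rows = []
        for tp, rate in rates.items():
            for roi in range(10):
                rows.append({"roi": roi, "timepoint": tp, "rate": rate,
                             "amplitude": 2 * rate, "tau": 0.7})
        return pd.DataFrame(rows)

    def test_flat_trajectory_is_one(self):
        m = self.make_metrics({"awake": 4.0, "t1": 4.0, "t2": 4.0})
        out = ca.recovery_normalization(m, baseline="awake")
        assert np.allclose(out["rate"], 1.0)

    def test_halved_rate_gives_half(self):
        m = self.make_metrics({"awake": 4.0, "t1": 2.0})
        out = ca.recovery_normalization(m, baseline="awake")
        assert out.loc["t1", "rate"] == pytest.approx(0.5)

    def test_staged_recovery_monotone(self):
        m = self.make_metrics({"awake": 4.0, "t1": 1.0, "t2": 2.0, "t3": 3.9})
        out = ca.recovery_normalization(m, baseline="awake")
        traj = out.loc[["t1", "t2", "t3"], "rate"].to_numpy()
        assert np.all(np.diff(traj) > 0)
        assert traj[-1] <= 1.0

    def test_exclusion_rules(self):
        m = self.make_metrics({"awake": 4.0, "t1": 2.0})
        m.loc[(m.roi == 0), "rate"] = 0.0       # no peaks at baseline
        m.loc[(m.roi == 1), "tau"] = 1.0 / 60   # below one frame
        out = ca.recovery_normalization(m, baseline="awake")
        assert out.loc["t1", "amplitude"] == pytest.approx(0.5)
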