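"""Activity metrics: PSTHs, evoked criteria, correlations, MI, rate stats."""

import numpy as np
import pytest

from cortexkit.analysis import (EvokedMetrics, criteria_check, ei_correlation,
                                evoked_metrics, mutual_information, psth,
                                rate_distribution_stats, rcu_ratio,
                                response_sparsity, select_l23_cells)
from cortexkit.network import SpikeRecording
from cortexkit.stimuli import BinarySignal, make_binary_signal


def make_recording(ids, times, duration, n_neurons=10, labels=("L5_E", "L5_I"),
                   pop_of=None):
    pop = np.zeros(n_neurons, dtype=int) if pop_of is None else np.asarray(pop_of)
    return SpikeRecording(neuron_ids=np.asarray(ids, dtype=np.int64),
                          times_ms=np.asarray(times, dtype=float),
                          duration=duration, pop_index=pop, pop_labels=list(labels))


class TestPSTH:
    def test_homogeneous_poisson_rate(self):
        """100 neurons at 10 Hz for 10 s: mean bin ~10 Hz within Poisson error."""
        rng = np.random.default_rng(0)
        n, dur, rate = 100, 10_000.0, 10.0
        counts = rng.poisson(rate * dur / 1000.0, n)
        times = np.concatenate([rng.uniform(0, dur, c) for c in counts])
        ids = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        p = psth(times, n, 0.0, dur, bin_ms=5.0, sigma_bins=0)
        se = np.sqrt(rate * 1000.0 / (5.0 * n)) / np.sqrt(len(p.values))
        assert p.values.mean() == pytest.approx(10.0, abs=4 * se + 0.1)

    def test_zero_sigma_is_raw_histogram(self):
        times = np.array([2.5, 7.5, 7.6])
        raw = psth(times, 1, 0.0, 10.0, bin_ms=5.0, sigma_bins=0)
        assert np.allclose(raw.values, [200.0, 400.0])

    def test_flat_histogram_normalizes_to_zero(self):
        times = np.arange(2.5, 1000.0, 5.0)  # one spike per bin
        p = psth(times, 1, 0.0, 1000.0, bin_ms=5.0, sigma_bins=0,
                 normalization="baseline_max")
        assert np.allclose(p.values, 0.0)

    def test_mass_conservation(self):
        """Sum(raw histogram) * bin equals total spikes / neurons / trials."""
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 1000.0, 500)
        p = psth(times, 4, 0.0, 1000.0, bin_ms=5.0, sigma_bins=0, n_trials=2)
        assert np.sum(p.values) * 5.0 / 1000.0 == pytest.approx(500 / (4 * 2))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            psth(np.array([1.0]), 0, 0.0, 10.0)


class TestEvokedMetrics:
    def rect_psth(self, base, peak, t0=500.0, t1=550.0):
        t = np.arange(2.5, 1000.0, 5.0)
        v = np.full_like(t, float(base))
        v[(t >= t0) & (t < t1)] = peak
        from cortexkit.analysis import PSTH
        return PSTH(bin_ms=5.0, times_ms=t, values=v, smoothing_sigma_bins=0)

    def test_rectangular_response_geometry(self):
        m = evoked_metrics(self.rect_psth(0.0, 8.0), stim_onset_ms=500.0)
        assert m.latency_ms <= 5.0
        assert abs(m.decay50_ms - 50.0) <= 5.0
        assert abs(m.decay25_ms - 50.0) <= 5.0
        assert m.decay25_ms >= m.decay50_ms >= m.latency_ms

    def test_evoked_ratio(self):
        m = evoked_metrics(self.rect_psth(2.0, 10.0), stim_onset_ms=500.0)
        assert m.R_E == pytest.approx(5.0)

    def test_scale_invariance(self):
        m1 = evoked_metrics(self.rect_psth(2.0, 10.0), 500.0)
        m2 = evoked_metrics(self.rect_psth(4.0, 20.0), 500.0)
        assert m1.latency_ms == m2.latency_ms
        assert m1.decay50_ms == m2.decay50_ms
        assert m1.R_E == pytest.approx(m2.R_E)

    def test_non_responsive_flagged(self):
        m = evoked_metrics(self.rect_psth(5.0, 5.0), 500.0)
        assert not m.responsive


class TestCriteriaCheck:
    def metrics(self, lat=10.0, d50=30.0, d25=60.0):
        return EvokedMetrics(latency_ms=lat, decay50_ms=d50, decay25_ms=d25,
                             R_E=5.0)

    def test_identical_model_passes(self):
        pops = ["L23_E", "L4_E"]
        ref = {p: self.metrics() for p in pops}
        res = criteria_check({p: self.metrics() for p in pops}, ref)
        assert res.overall

    def test_late_latency_fails_one_flag(self):
        ref = {"L23_E": self.metrics(), "L4_E": self.metrics()}
        model = {"L23_E": self.metrics(lat=25.0), "L4_E": self.metrics()}
        res = criteria_check(model, ref)
        assert not res.overall
        assert not res.latency_pass["L23_E"]
        assert res.latency_pass["L4_E"]

    def test_l1_excluded(self):
        ref = {"L23_E": self.metrics()}
        model = {"L1_I": self.metrics(lat=500.0), "L23_E": self.metrics()}
        res = criteria_check(model, ref)
        assert res.overall  # L1_I never evaluated

    def test_secondary_rise_fails(self):
        from cortexkit.analysis import PSTH
        t = np.arange(2.5, 300.0, 5.0)
        v = np.zeros_like(t)
        v[(t >= 10) & (t < 30)] = 1.0       # primary response (normalized)
        v[(t >= 80) & (t < 90)] = 0.40      # late bump > 35%
        p = PSTH(bin_ms=5.0, times_ms=t, values=v, normalization="baseline_max")
        ref = {"L4_E": self.metrics()}
        model = {"L4_E": self.metrics()}
        res = criteria_check(model, ref, model_psths={"L4_E": p},
                             stim_onset_ms=0.0)
        assert not res.secondary_rise_pass["L4_E"]
        assert not res.overall

    def test_slack_boundaries_inclusive(self):
        ref = {"L4_E": self.metrics(lat=10.0, d50=30.0, d25=60.0)}
        model = {"L4_E": self.metrics(lat=20.0, d50=40.0, d25=100.0)}
        assert criteria_check(model, ref).overall

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            criteria_check({"L4_E": self.metrics()}, {})


class TestRates:
    def test_rcu_identity_and_scaling(self):
        r, flags = rcu_ratio([1.0, 2.0], [1.0, 2.0])
        assert np.allclose(r, 1.0)
        r, _ = rcu_ratio([2.0, 4.0], [1.0, 2.0])
        assert np.allclose(r, 2.0)

    def test_rcu_degenerate_flags(self):
        r, flags = rcu_ratio([0.0, 1.0], [0.0, 0.0])
        assert np.isnan(r[0]) and np.isinf(r[1])
        assert flags.all()

    def test_sparsity_half_silent(self):
        ids = np.arange(5)
        rec = make_recording(ids, np.linspace(10, 50, 5), 100.0)
        assert response_sparsity(rec, "L5_E", (0.0, 100.0)) == 0.5

    def test_rate_stats_degenerate_identical_rates(self):
        ids = np.tile(np.arange(10), 4)
        times = np.sort(np.tile(np.linspace(10, 900, 4), 10))
        rec = make_recording(ids, np.sort(times), 1000.0)
        stats = rate_distribution_stats(rec)["L5_E"]
        assert stats.lognorm_sigma == pytest.approx(0.0, abs=1e-12)
        assert stats.sparsity == 1.0

    def test_lognormal_recovery(self):
        """Parameters of a known lognormal recovered within 5% at n = 1e4."""
        rng = np.random.default_rng(2)
        mu, sigma = 0.5, 0.8
        rates = rng.lognormal(mu, sigma, 10_000)
        duration = 10_000.0
        counts = np.round(rates * duration / 1000.0).astype(int)
        ids = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        times = np.sort(rng.uniform(0, duration, len(ids)))
        rec = make_recording(ids, times, duration, n_neurons=10_000)
        stats = rate_distribution_stats(rec)["L5_E"]
        assert stats.lognorm_mu == pytest.approx(mu, abs=0.05 * sigma + 0.02)
        assert stats.lognorm_sigma == pytest.approx(sigma, rel=0.05)


class TestEICorrelation:
    def test_identical_histograms_r_one(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 5000.0, 400))
        ids = np.concatenate([np.zeros(400, int), np.ones(400, int)])
        times = np.concatenate([t, t])
        rec = make_recording(ids, times, 5000.0, n_neurons=2, pop_of=[0, 1])
        out = ei_correlation(rec)
        assert out["L5"] == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(4)
        te = np.sort(rng.uniform(0, 60_000.0, 3000))
        ti = np.sort(rng.uniform(0, 60_000.0, 3000))
        ids = np.concatenate([np.zeros(3000, int), np.ones(3000, int)])
        rec = make_recording(ids, np.concatenate([te, ti]), 60_000.0,
                             n_neurons=2, pop_of=[0, 1])
        assert abs(ei_correlation(rec)["L5"]) < 0.05

    def test_antiphase_square_waves_r_minus_one(self):
        # spikes in alternating 100 ms blocks
        te, ti = [], []
        for k in range(50):
            base = k * 200.0
            te.extend(np.linspace(base + 1, base + 99, 40))
            ti.extend(np.linspace(base + 101, base + 199, 40))
        ids = np.concatenate([np.zeros(len(te), int), np.ones(len(ti), int)])
        rec = make_recording(ids, np.concatenate([te, ti]), 10_000.0,
                             n_neurons=2, pop_of=[0, 1])
        assert ei_correlation(rec, sigma_bins=0)["L5"] < -0.9


class TestMutualInformation:
    def balanced_signal(self, n_states=40, dwell=2.5):
        switches = np.arange(1, n_states) * dwell
        return BinarySignal(switch_times_s=switches,
                            duration_s=n_states * dwell, initial_state=0)

    def test_deterministic_channel_one_bit(self):
        """Counts that copy a balanced signal carry exactly 1 bit."""
        sig = self.balanced_signal()
        spikes = {}
        t = np.arange(0.025, sig.duration_s, 0.05)
        states = sig.state_at(t)
        spikes[0] = t[states == 1]  # one spike in every up bin, none in down
        res = mutual_information(sig, spikes, bin_ms=50.0, n_shuffles=50,
                                 seed=0)
        assert res.mi_bits[0] == pytest.approx(1.0, abs=1e-9)
        assert res.significant[0]

    def test_count_relabeling_invariance(self):
        """Doubling every bin count leaves MI unchanged (bijection)."""
        sig = self.balanced_signal()
        t = np.arange(0.025, sig.duration_s, 0.05)
        states = sig.state_at(t)
        up_bins = t[states == 1]
        one = {0: up_bins}
        two = {0: np.sort(np.concatenate([up_bins, up_bins + 0.001]))}
        r1 = mutual_information(sig, one, bin_ms=50.0, n_shuffles=10, seed=1)
        r2 = mutual_information(sig, two, bin_ms=50.0, n_shuffles=10, seed=1)
        assert r1.mi_bits[0] == pytest.approx(r2.mi_bits[0], abs=1e-12)

    def test_independent_spikes_non_significant(self):
        sig = make_binary_signal(100.0, seed=5)
        rng = np.random.default_rng(6)
        spikes = {c: np.sort(rng.uniform(0, 100.0, rng.poisson(200)))
                  for c in range(20)}
        res = mutual_information(sig, spikes, bin_ms=50.0, n_shuffles=100,
                                 seed=7)
        assert res.significant.mean() <= 0.15

    def test_silent_cells_excluded(self):
        sig = self.balanced_signal()
        res = mutual_information(sig, {0: np.array([]), 1: np.array([1.0])},
                                 n_shuffles=10, seed=0)
        assert 0 not in res.cell_ids and 1 in res.cell_ids

    def test_single_state_rejected(self):
        sig = BinarySignal(switch_times_s=np.array([]), duration_s=10.0)
        with pytest.raises(ValueError):
            mutual_information(sig, {0: np.array([1.0])}, seed=0)

    def test_shuffle_false_positive_rate(self):
        """FPR of the circular-shift control stays within alpha + 2% on
        signal-independent spikes (500 cells over 20 seeds)."""
        n_sig = 0
        n_tot = 0
        for seed in range(20):
            sig = make_binary_signal(150.0, seed=100 + seed)
            rng = np.random.default_rng(200 + seed)
            spikes = {c: np.sort(rng.uniform(0, 150.0, rng.poisson(300)))
                      for c in range(25)}
            res = mutual_information(sig, spikes, bin_ms=50.0, n_shuffles=100,
                                     alpha=0.05, seed=300 + seed)
            n_sig += res.significant.sum()
            n_tot += len(res.significant)
        assert n_tot == 500
        assert n_sig / n_tot <= 0.05 + 0.02


class TestSelectL23:
    def make_cohort(self):
        dt = 0.1
        onset, dur = 100.0, 50.0
        n_steps = int(400 / dt)
        flat = np.full(n_steps, -70.0)
        steep = flat.copy()
        i0 = int(onset / dt)
        steep[i0 + 10: i0 + 30] += np.linspace(0, 8, 20)  # 4 mV/ms rise
        voltages = {0: steep, 1: flat, 2: steep, 3: steep}
        control_spikes = {2: np.array([120.0])}  # spikes during stimulus
        opto_spikes = {}
        innervated = {0, 1, 2}
        return voltages, control_spikes, opto_spikes, innervated, onset, dur

    def test_three_criteria_intersection(self):
        v, cs, os_, inn, onset, dur = self.make_cohort()
        sel = select_l23_cells(cs, os_, v, inn, onset, dur)
        # 0: passes all; 1: no dV/dt; 2: spiked; 3: not innervated
        assert sel == {0}

    def test_opto_run_spiking_excludes(self):
        v, cs, os_, inn, onset, dur = self.make_cohort()
        os_[0] = np.array([130.0])
        assert 0 not in select_l23_cells(cs, os_, v, inn, onset, dur)
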