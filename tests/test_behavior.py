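"""Echo-chirp simulator and behavioral analysis: rates, PSTHs, invariance, bootstrap."""

import numpy as np
import pytest
from scipy.stats import kruskal

from beatchirp.behavior import (
    behavioral_invariance,
    behavioral_psth,
    block_bootstrap,
    chirp_rate,
    per_chirp_counts,
)
from beatchirp.behavior_sim import (
    CHIRP_DELTA_F_RANGE,
    CHIRP_DELTA_T_RANGE,
    EchoParams,
    EchoSeries,
    emitted_chirp_stats,
    simulate_echoes,
)
from beatchirp.core import Trace
from beatchirp.errors import InputError


def series(emitted, stim=(1.0,), duration=3.0, trial=0, f_beat=2.0, phase=0.0):
    return EchoSeries(trial, np.asarray(stim, float), np.asarray(emitted, float),
                      duration, f_beat, phase)


class TestSimulateEchoes:
    def test_zero_drive_baseline_rate(self):
        p = EchoParams(baseline_emission_rate=0.5, echo_gain=2.0, n_trials=500, seed=3)
        out = simulate_echoes(np.array([1.0]), 3.0, 0.0, p, 2.0, 0.0)
        total = sum(s.emitted_chirp_times.size for s in out)
        expect = 0.5 * 3.0 * 500
        assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_full_drive_recovers_echo_gain(self):
        p = EchoParams(baseline_emission_rate=0.0, echo_gain=2.0, n_trials=500, seed=4)
        out = simulate_echoes(np.array([1.0]), 3.0, 1.0, p, 2.0, 0.0)
        per_chirp = np.array([s.emitted_chirp_times.size for s in out])
        se = np.sqrt(2.0 / 500)
        assert abs(per_chirp.mean() - 2.0) < 3 * se

    def test_echo_latencies_within_response_window(self):
        p = EchoParams(baseline_emission_rate=0.0, n_trials=200, seed=5)
        out = simulate_echoes(np.array([1.0]), 3.0, 1.0, p, 2.0, 0.0)
        for s in out:
            if s.emitted_chirp_times.size:
                rel = s.emitted_chirp_times - 1.0
                assert np.all((rel > 0) & (rel < 1.0))

    def test_seeded_reproducibility_byte_for_byte(self, tmp_path):
        from beatchirp.io import write_echo_series_csv

        p = EchoParams(n_trials=50, seed=6)
        a = simulate_echoes(np.array([1.0]), 3.0, 0.5, p, 2.0, 0.0)
        b = simulate_echoes(np.array([1.0]), 3.0, 0.5, p, 2.0, 0.0)
        write_echo_series_csv(tmp_path / "a.csv", a)
        write_echo_series_csv(tmp_path / "b.csv", b)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_invalid_drive_rejected(self):
        with pytest.raises(InputError):
            simulate_echoes(np.array([1.0]), 3.0, 1.5, EchoParams(n_trials=2), 2.0, 0.0)


class TestEmittedChirpStats:
    def make_series(self, seed, n=40):
        rng = np.random.default_rng(seed)
        out = []
        for f in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0):
            out.append(series(np.sort(rng.uniform(0, 3, n)), f_beat=f, phase=0.0))
        return out

    def test_support_bounds(self):
        df = emitted_chirp_stats(self.make_series(0), seed=1)
        assert df.delta_f_hz.between(*CHIRP_DELTA_F_RANGE).all()
        assert df.delta_t_s.between(*CHIRP_DELTA_T_RANGE).all()

    def test_characteristics_frequency_independent(self):
        """Kruskal-Wallis across beat-frequency groups: null by construction.

        Under the null, exactly 5% of runs are significant at alpha=0.05 in
        expectation, so the non-significant fraction is compared against the
        3-sigma binomial lower bound of the nominal 95% (200 runs: >= 90%).
        """
        ok_f = ok_t = 0
        n_runs = 200
        for seed in range(n_runs):
            df = emitted_chirp_stats(self.make_series(seed, n=30), seed=seed)
            groups_f = [g.delta_f_hz.values for _, g in df.groupby("f_beat")]
            groups_t = [g.delta_t_s.values for _, g in df.groupby("f_beat")]
            ok_f += kruskal(*groups_f).pvalue > 0.05
            ok_t += kruskal(*groups_t).pvalue > 0.05
        lower = n_runs * (0.95 - 3 * np.sqrt(0.05 * 0.95 / n_runs))
        assert ok_f >= lower
        assert ok_t >= lower


class TestChirpRate:
    def test_three_chirps_in_window(self):
        s = series([1.2, 1.5, 1.9], stim=[1.0])
        assert chirp_rate([s]) == pytest.approx(3.0)

    def test_no_emissions_zero(self):
        assert chirp_rate([series([])]) == 0.0

    def test_poisson_rate_recovery(self):
        p = EchoParams(baseline_emission_rate=0.8, echo_gain=0.0, n_trials=500, seed=8)
        out = simulate_echoes(np.array([1.0]), 3.0, 0.0, p, 2.0, 0.0)
        est = chirp_rate(out)
        se = np.sqrt(0.8 / 500)
        assert abs(est - 0.8) < 3 * se

    def test_no_stimulus_chirps_rejected(self):
        with pytest.raises(InputError):
            per_chirp_counts([series([], stim=[])])


class TestBehavioralInvariance:
    def test_identical_psths_score_one(self):
        t = np.arange(0, 1, 0.01) + 0.005
        stimuli = [Trace(t, np.sin(2 * np.pi * 2 * t + k)) for k in range(8)]
        psths = [Trace(t, np.exp(-((t - 0.3) ** 2) / 0.02))] * 8
        assert behavioral_invariance(psths, stimuli) == 1.0

    def test_stimulus_matched_psths_score_zero(self):
        t = np.arange(0, 1, 0.01) + 0.005
        stimuli = [Trace(t, np.sin(2 * np.pi * 2 * t + k)) for k in range(8)]
        psths = [Trace(t, 5.0 * s.values + 10.0) for s in stimuli]
        assert behavioral_invariance(psths, stimuli) == pytest.approx(0.0, abs=1e-12)


class TestBlockBootstrap:
    def test_constant_series_zero_se(self):
        se, _ = block_bootstrap(np.full(100, 2.5), n_boot=200, seed=1)
        assert se == 0.0

    def test_iid_series_matches_closed_form(self, rng):
        """Mean of 310 iid normals: bootstrap SE within 15% of sigma/sqrt(n).

        A single 310-point series holds only ~10 independent blocks, so the
        bootstrap SE of one series has ~25% sampling CV; averaging over 20
        independent series makes the 15% band a ~3-sigma check.
        """
        ses = [
            block_bootstrap(rng.normal(0.0, 2.0, size=310), np.mean,
                            block_size=31, n_boot=400, seed=k)[0]
            for k in range(20)
        ]
        assert np.mean(ses) == pytest.approx(2.0 / np.sqrt(310), rel=0.15)

    def test_ar1_series_inflates_se_over_naive(self, rng):
        n, phi = 620, 0.6
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        naive = x.std(ddof=1) / np.sqrt(n)
        se, _ = block_bootstrap(x, np.mean, block_size=31, n_boot=1000, seed=3)
        assert se > naive

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            block_bootstrap(np.ones(10), block_size=31)

    def test_percentile_interval_brackets_mean(self, rng):
        x = rng.normal(5.0, 1.0, size=310)
        _, (lo, hi) = block_bootstrap(x, np.mean, n_boot=1000, seed=4)
        assert lo < x.mean() < hi
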