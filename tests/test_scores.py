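"""Distance metric, detectability, invariance score, response-duration fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from beatchirp.core import Trace
from beatchirp.errors import InputError, UndefinedMetricError
from beatchirp.scores import (
    AnalysisWindow,
    distance,
    fit_duration_powerlaw,
    inter_chirp_distance,
    invariance_score,
    mean_pairwise_distance,
    neuronal_detectability,
    response_duration,
    stimulus_detectability,
)


def trace(values, dt=0.001):
    values = np.asarray(values, dtype=float)
    return Trace(np.arange(values.size) * dt, values)


WIN = AnalysisWindow(0.0, 1.0)


def brute_distance(x, y):
    """Direct arithmetic re-implementation of the normalized distance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    num = np.mean((x - x.mean() - y + y.mean()) ** 2)
    den = max((x.max() - x.min()) / 2, (y.max() - y.min()) / 2)
    return num / den


class TestDistance:
    def test_self_distance_zero(self, rng):
        x = trace(rng.normal(size=50))
        assert distance(x, x, WIN) == 0.0

    def test_constant_offset_invisible(self, rng):
        v = rng.normal(size=50)
        assert distance(trace(v), trace(v + 3.7), WIN) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # x=(0,1,0), y=(0,0,1): mean-subtracted difference (0,1,-1),
        # mean square 2/3, half peak-to-peak 1/2 -> D = 4/3
        assert distance(trace([0, 1, 0]), trace([0, 0, 1]), WIN) == pytest.approx(
            4.0 / 3.0, abs=1e-12
        )

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(120):
            n = rng.integers(3, 40)
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert distance(trace(x), trace(y), WIN) == pytest.approx(
                brute_distance(x, y), abs=1e-12
            )

    def test_both_constant_undefined(self):
        with pytest.raises(UndefinedMetricError):
            distance(trace(np.ones(10)), trace(np.zeros(10)), WIN)

    def test_nan_samples_excluded_pairwise(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        xn, yn = x.copy(), y.copy()
        xn[3], yn[17] = np.nan, np.nan
        keep = np.ones(30, bool)
        keep[[3, 17]] = False
        assert distance(trace(xn), trace(yn), WIN) == pytest.approx(
            brute_distance(x[keep], y[keep]), abs=1e-12
        )


class TestNeuronalDetectability:
    def win(self):
        return AnalysisWindow(0.0, 1.0)

    def test_equal_ranges_zero(self, rng):
        x = trace(rng.normal(size=40))
        assert neuronal_detectability(x, x, self.win(), self.win()) == 0.0

    def test_silent_beat_full_detectability(self):
        chirp = trace(np.r_[np.zeros(10), np.ones(10)])
        beat = trace(np.zeros(20))
        assert neuronal_detectability(chirp, beat, self.win(), self.win()) == 1.0

    def test_three_to_one_ratio(self):
        chirp = trace([0.0, 3.0])
        beat = trace([0.0, 1.0])
        assert neuronal_detectability(chirp, beat, self.win(), self.win()) == pytest.approx(0.5)

    @settings(max_examples=60, derandomize=True)
    @given(
        x=arrays(float, 12, elements=st.floats(0, 100)),
        y=arrays(float, 12, elements=st.floats(0, 100)),
    )
    def test_unit_interval_and_symmetry(self, x, y):
        if np.ptp(x) + np.ptp(y) == 0:
            return
        d1 = neuronal_detectability(trace(x), trace(y), self.win(), self.win())
        d2 = neuronal_detectability(trace(y), trace(x), self.win(), self.win())
        assert 0.0 <= d1 <= 1.0
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_both_flat_undefined(self):
        with pytest.raises(UndefinedMetricError):
            neuronal_detectability(trace(np.ones(5)), trace(np.ones(5)), self.win(), self.win())


class TestInvarianceScore:
    def eight(self, rng):
        return [trace(np.sin(np.linspace(0, 7, 60) + k)) for k in range(8)]

    def test_identical_responses_score_one(self, rng):
        stimuli = self.eight(rng)
        responses = [trace(np.cos(np.linspace(0, 7, 60)))] * 8
        assert invariance_score(responses, stimuli, WIN) == 1.0

    def test_identity_encoding_scores_zero(self, rng):
        stimuli = self.eight(rng)
        assert invariance_score(list(stimuli), stimuli, WIN) == pytest.approx(0.0, abs=1e-12)

    def test_scale_free_in_response_units(self, rng):
        """Encoding the stimuli in different physical units (x1000 gain) must not
        change the score."""
        stimuli = self.eight(rng)
        responses = [trace(s.values * 1000.0) for s in stimuli]
        assert invariance_score(responses, stimuli, WIN) == pytest.approx(0.0, abs=1e-12)

    def test_identical_stimuli_undefined(self, rng):
        stim = [trace(np.sin(np.linspace(0, 7, 60)))] * 8
        with pytest.raises(UndefinedMetricError):
            invariance_score(stim, stim, WIN)


class TestResponseDuration:
    def test_identical_traces_undefined(self):
        t = np.arange(0, 1, 1e-3)
        x = Trace(t, np.sin(2 * np.pi * 3 * t))
        assert np.isnan(response_duration(x, x, onset=0.5, beat_epoch=(0.0, 0.4)))

    def test_square_bump_duration_recovered(self, rng):
        t = np.arange(0, 2, 1e-3)
        base = rng.normal(0, 0.05, size=t.size)
        resp = base.copy()
        resp[(t >= 1.0) & (t < 1.25)] += 2.0
        d = response_duration(Trace(t, resp), Trace(t, base * 0 + base.mean()),
                              onset=1.0, beat_epoch=(0.1, 0.9))
        assert d == pytest.approx(0.25, abs=0.01)

    def test_gap_tolerance_bridges_short_dropouts(self):
        t = np.arange(0, 2, 1e-3)
        resp = np.zeros_like(t)
        resp[(t >= 1.0) & (t < 1.1)] = 1.0
        resp[(t >= 1.12) & (t < 1.2)] = 1.0  # 20 ms dropout inside the response
        ref = Trace(t, np.zeros_like(t))
        strict = response_duration(Trace(t, resp), ref, 1.0, (0.1, 0.9))
        bridged = response_duration(Trace(t, resp), ref, 1.0, (0.1, 0.9), max_gap=0.03)
        assert strict == pytest.approx(0.1, abs=0.005)
        assert bridged == pytest.approx(0.2, abs=0.005)

    def test_powerlaw_exponent_recovery(self, rng):
        """d = 0.05 f^-0.8 with 2% noise: fitted exponent within +-0.05."""
        f = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
        d = 0.05 * f**-0.8 * (1 + rng.normal(0, 0.02, size=f.size))
        fit = fit_duration_powerlaw(f, d)
        assert fit.b == pytest.approx(-0.8, abs=0.05)
        assert fit.r_squared > 0.99

    def test_undefined_durations_excluded(self):
        f = np.array([1.0, 2.0, 4.0, 8.0])
        d = np.array([0.05, np.nan, 0.02, 0.012])
        fit = fit_duration_powerlaw(f, d)
        assert fit.b < 0

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(InputError):
            fit_duration_powerlaw(np.array([1.0, 2.0]), np.array([0.05, 0.03]))


class TestStimulusLevel:
    def test_identical_waveforms_zero_detectability(self):
        t = np.arange(0, 1, 1e-4)
        beat = Trace(t, 0.34 * np.sin(2 * np.pi * 2 * t))
        assert stimulus_detectability(beat, beat, 2.0, chirp_onset=0.25) == 0.0

    def test_identical_copies_zero_inter_chirp_distance(self):
        t = np.arange(0, 0.02, 1e-4)
        w = [Trace(t, np.sin(2 * np.pi * 60 * t)) for _ in range(8)]
        assert inter_chirp_distance(w, 0.014) == 0.0

    def test_single_waveform_rejected(self):
        t = np.arange(0, 0.02, 1e-4)
        with pytest.raises(InputError):
            inter_chirp_distance([Trace(t, np.sin(t))], 0.014)
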