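"""Beat/chirp AM synthesis: periodicity, chirp profile geometry, phase bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from beatchirp.errors import ParameterError
from beatchirp.stimulus import (
    AMWaveform,
    StimulusSpec,
    chirp_profile_area,
    insert_chirp,
    make_beat,
    make_chirp_profile,
    phase_advance,
    phase_grid,
)


def beat_spec(f_beat=2.0, **kw):
    return StimulusSpec(f_beat=f_beat, **kw)


class TestMakeBeat:
    def test_exact_cycles_and_contrast(self):
        am = make_beat(beat_spec(f_beat=2.0, total_duration=1.0))
        # 2 full AM cycles in 1 s; the 10 kHz grid hits the sine peaks exactly
        zero_up = np.flatnonzero((am.values[:-1] < 0) & (am.values[1:] >= 0))
        assert zero_up.size == 1  # one interior upward crossing => 2 cycles
        assert am.values.max() == pytest.approx(0.34, abs=1e-12)

    def test_periodicity_one_beat_cycle(self):
        spec = beat_spec(f_beat=4.0, total_duration=2.0)
        am = make_beat(spec)
        lag = int(round(spec.sample_rate / spec.f_beat))
        r = np.corrcoef(am.values[:-lag], am.values[lag:])[0, 1]
        assert r > 0.999

    def test_envelope_matches_two_carrier_sum(self):
        """Oracle: the AM equals the Hilbert envelope modulation of an explicit
        two-carrier sum (receiver EOD at f1 plus a weak emitter EOD at f1 - f_beat)."""
        f1, f_beat, ratio, fs = 800.0, 8.0, 0.02, 40_000.0
        t = np.arange(0.0, 2.0, 1.0 / fs)
        carrier = np.sin(2 * np.pi * f1 * t) + ratio * np.sin(2 * np.pi * (f1 - f_beat) * t)
        env = np.abs(hilbert(carrier))
        mod = env - env.mean()
        # envelope modulation of the sum is ratio * cos(2 pi f_beat t)
        expected = ratio * np.cos(2 * np.pi * f_beat * t)
        edge = int(0.1 * fs)  # discard Hilbert edge artifacts
        rms = np.sqrt(np.mean((mod - expected)[edge:-edge] ** 2))
        assert rms / ratio < 0.01
        # and our synthesized beat is that same sinusoid (phase convention: sin)
        spec = beat_spec(f_beat=f_beat, contrast=ratio, total_duration=1.0)
        am = make_beat(spec)
        assert np.allclose(
            am.values,
            ratio * np.cos(2 * np.pi * f_beat * (am.times - 1 / (4 * f_beat))),
            atol=1e-12,
        )

    def test_rejects_chirp_spec(self):
        with pytest.raises(ParameterError):
            make_beat(StimulusSpec(f_beat=2.0, chirp_phase=0.0))


class TestChirpProfile:
    def test_peak_and_duration(self):
        prof = make_chirp_profile(60.0, 0.014)
        assert prof.excursion.max() == pytest.approx(60.0, rel=1e-6)
        nz = np.flatnonzero(prof.excursion > 0)
        support = prof.times[nz[-1]] - prof.times[nz[0]]
        assert support == pytest.approx(0.014, abs=2.5e-4)  # +- one sample

    def test_zero_excursion(self):
        prof = make_chirp_profile(0.0, 0.014)
        assert np.all(prof.excursion == 0)

    def test_area_matches_closed_form(self):
        prof = make_chirp_profile(60.0, 0.014, sample_rate=100_000.0)
        assert prof.area == pytest.approx(chirp_profile_area(60.0, 0.014), rel=1e-3)

    def test_invalid_duration(self):
        with pytest.raises(ParameterError):
            make_chirp_profile(60.0, 0.0)


class TestInsertChirp:
    def test_zero_delta_f_reduces_to_beat_bitwise(self):
        spec = StimulusSpec(f_beat=2.0, chirp_phase=90.0, delta_f=0.0)
        chirped = insert_chirp(spec)
        beat = make_beat(StimulusSpec(f_beat=2.0, total_duration=spec.duration))
        assert np.array_equal(chirped.values, beat.values)

    def test_causal_perturbation(self):
        spec = StimulusSpec(f_beat=2.0, chirp_phase=45.0)
        chirped = insert_chirp(spec)
        beat = make_beat(StimulusSpec(f_beat=2.0, total_duration=spec.duration))
        i_on = int(np.floor(spec.chirp_onset_time * spec.sample_rate))
        diff = chirped.values - beat.values
        assert np.all(diff[: i_on - 1] == 0)
        assert np.any(diff[i_on:] != 0)

    @pytest.mark.parametrize("phase", [0.0, 90.0, 225.0])
    def test_post_chirp_phase_advance_matches_excursion_integral(self, phase):
        spec = StimulusSpec(f_beat=4.0, chirp_phase=phase)
        chirped = insert_chirp(spec)
        advance = phase_advance(spec)  # 2 pi * trapezoidal integral oracle
        t = chirped.times
        after = t > spec.chirp_onset_time + spec.delta_t
        expected = spec.contrast * np.sin(2 * np.pi * spec.f_beat * t[after] + advance)
        # agreement within one sample of beat phase
        tol = spec.contrast * 2 * np.pi * spec.f_beat / spec.sample_rate
        assert np.max(np.abs(chirped.values[after] - expected)) < tol

    @pytest.mark.parametrize("phase", [0.0, 45.0, 90.0, 135.0])
    def test_opposite_phases_are_sign_mirrors(self, phase):
        """The four phases not plotted in the canonical figure layout are sign/time
        mirror images: chirp at phase+180 equals minus the phase waveform,
        time-shifted by half a beat period."""
        f = 2.0
        dur = 3.0
        a = insert_chirp(StimulusSpec(f_beat=f, chirp_phase=phase, total_duration=dur))
        b = insert_chirp(StimulusSpec(f_beat=f, chirp_phase=phase + 180.0, total_duration=dur))
        shift = int(round(0.5 / f * a.spec.sample_rate))  # half beat period
        assert np.allclose(b.values[shift:], -a.values[:-shift], atol=1e-9)

    def test_chirp_outside_duration_rejected(self):
        with pytest.raises(ParameterError):
            StimulusSpec(f_beat=1.0, chirp_phase=315.0, total_duration=1.0)


class TestPhaseGrid:
    def test_eight_phases(self):
        specs = phase_grid(StimulusSpec(f_beat=2.0, chirp_phase=0.0))
        assert [s.chirp_phase for s in specs] == [0, 45, 90, 135, 180, 225, 270, 315]

    def test_shared_prechirp_beat(self):
        base = StimulusSpec(f_beat=2.0, chirp_phase=0.0, total_duration=3.0)
        beat = make_beat(StimulusSpec(f_beat=2.0, total_duration=3.0))
        for spec in phase_grid(base):
            am = insert_chirp(spec)
            i_on = int(np.floor(spec.chirp_onset_time * spec.sample_rate))
            assert np.array_equal(am.values[: i_on - 1], beat.values[: i_on - 1])


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw, field",
        [
            (dict(f_beat=0.0), "f_beat"),
            (dict(f_beat=2.0, delta_t=-1.0), "delta_t"),
            (dict(f_beat=2.0, contrast=0.0), "contrast"),
            (dict(f_beat=2.0, sample_rate=100.0), "sample_rate"),
        ],
    )
    def test_errors_name_the_field(self, kw, field):
        with pytest.raises(ParameterError, match=field):
            StimulusSpec(**kw)

    @settings(max_examples=50, derandomize=True)
    @given(phase=st.floats(-1000, 1000, allow_nan=False))
    def test_phase_reduced_mod_360(self, phase):
        spec = StimulusSpec(f_beat=2.0, chirp_phase=phase)
        assert 0.0 <= spec.chirp_phase < 360.0

    @settings(max_examples=25, derandomize=True)
    @given(
        f_beat=st.sampled_from([1.0, 2.0, 8.0, 32.0, 128.0]),
        phase=st.sampled_from([0.0, 45.0, 180.0, 315.0]),
        contrast=st.floats(0.14, 0.61),
    )
    def test_amplitude_bounded_by_contrast(self, f_beat, phase, contrast):
        am = insert_chirp(StimulusSpec(f_beat=f_beat, chirp_phase=phase, contrast=contrast))
        assert np.max(np.abs(am.values)) <= contrast * (1 + 1e-9)
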