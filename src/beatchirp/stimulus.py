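"""Beat / chirp amplitude-modulation stimulus synthesis.

Two weakly electric fish with electric-organ-discharge (EOD) frequencies f1
and f2 produce, by interference, a sinusoidal amplitude modulation (the
*beat*) of frequency ``f_beat = |f1 - f2|`` on the receiver's skin.  A *small
chirp* is a brief (~14 ms) transient increase of the emitter's EOD frequency
by up to ``delta_f`` (~60 Hz); seen through the beat it is a rapid phase sweep
that perturbs the modulation and permanently phase-advances the beat.

This module synthesizes the AM directly in the envelope domain:

    AM(t) = contrast * sin(Phi(t)),
    Phi(t) = 2*pi * Integral_0^t [f_beat + excursion(tau)] dtau

with excursion(t) the chirp's instantaneous frequency excursion.  Phase
convention: beat phase 0 deg is the upward zero crossing of the AM (phi0 = 0
at t = 0), and ``chirp_phase`` is the beat phase at chirp *onset*, i.e. the
start of the excursion window.

The excursion profile is a raised Gaussian supported exactly on the chirp
window: with sigma = delta_t/4 and center t_c,

    excursion(t) = delta_f * (exp(-(t-t_c)^2 / (2 sigma^2)) - e^-2) / (1 - e^-2)

for |t - t_c| <= 2 sigma and 0 outside, so the peak is exactly delta_f, the
duration (support width, the +-2 sigma definition) is exactly delta_t, and the
perturbation is causal: the waveform is bit-identical to the unperturbed beat
before chirp onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import erf

from .errors import ParameterError

#: the 8 chirp phases used throughout (degrees on the beat cycle)
PHASE_GRID_DEG = tuple(range(0, 360, 45))

#: default peak EOD-frequency excursion of a small (type II) chirp, Hz
DEFAULT_DELTA_F = 60.0
#: default chirp duration, s
DEFAULT_DELTA_T = 0.014
#: default AM contrast, mV/cm (population-average stimulus intensity)
DEFAULT_CONTRAST = 0.34
#: default sampling rate, Hz (matches 10 kHz digitization of the recordings)
DEFAULT_SAMPLE_RATE = 10_000.0

_EDGE = np.exp(-2.0)  # Gaussian value at +-2 sigma, subtracted off


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one beat stimulus, optionally with a chirp.

    ``chirp_phase is None`` means a beat-only stimulus.  ``total_duration``
    defaults to a rule guaranteeing ``n_beat_cycles_before_chirp`` unperturbed
    cycles before the chirp and at least one full cycle after chirp onset
    (minimum 1 s), so beat-only reference windows always exist.
    """

    f_beat: float
    chirp_phase: float | None = None  # degrees, reduced mod 360
    delta_f: float = DEFAULT_DELTA_F
    delta_t: float = DEFAULT_DELTA_T
    contrast: float = DEFAULT_CONTRAST
    sample_rate: float = DEFAULT_SAMPLE_RATE
    total_duration: float | None = None
    n_beat_cycles_before_chirp: int = 2

    def __post_init__(self) -> None:
        if self.chirp_phase is not None:
            object.__setattr__(self, "chirp_phase", float(self.chirp_phase) % 360.0)
        self.validate()

    def validate(self) -> None:
        if not self.f_beat > 0:
            raise ParameterError(f"f_beat must be > 0, got {self.f_beat}")
        if not self.delta_t > 0:
            raise ParameterError(f"delta_t must be > 0, got {self.delta_t}")
        if self.delta_f < 0:
            raise ParameterError(f"delta_f must be >= 0, got {self.delta_f}")
        if not self.contrast > 0:
            raise ParameterError(f"contrast must be > 0, got {self.contrast}")
        if self.sample_rate < 20.0 / self.delta_t:
            raise ParameterError(
                f"sample_rate must be >= 20/delta_t = {20.0 / self.delta_t:.1f} Hz "
                f"to resolve the chirp, got {self.sample_rate}"
            )
        if self.n_beat_cycles_before_chirp < 1:
            raise ParameterError(
                "n_beat_cycles_before_chirp must be >= 1, "
                f"got {self.n_beat_cycles_before_chirp}"
            )
        if self.total_duration is not None:
            if not self.total_duration > 0:
                raise ParameterError(
                    f"total_duration must be > 0, got {self.total_duration}"
                )
            if self.chirp_phase is not None and (
                self.chirp_onset_time + self.delta_t > self.total_duration
            ):
                raise ParameterError(
                    "total_duration too short: chirp scheduled outside "
                    f"[0, {self.total_duration}] (onset {self.chirp_onset_time:.4f} s)"
                )

    @property
    def beat_period(self) -> float:
        return 1.0 / self.f_beat

    @property
    def chirp_onset_time(self) -> float:
        """Chirp onset scheduled so the beat phase at onset equals chirp_phase."""
        if self.chirp_phase is None:
            raise ParameterError("beat-only spec has no chirp_onset_time")
        return (self.n_beat_cycles_before_chirp + self.chirp_phase / 360.0) / self.f_beat

    @property
    def duration(self) -> float:
        """Resolved total duration (s)."""
        if self.total_duration is not None:
            return self.total_duration
        if self.chirp_phase is None:
            return max(1.0, (self.n_beat_cycles_before_chirp + 2) / self.f_beat)
        return max(1.0, self.chirp_onset_time + self.delta_t + 1.25 * self.beat_period)

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate


@dataclass(frozen=True)
class ChirpFrequencyProfile:
    """Instantaneous EOD-frequency excursion of the emitter during a chirp."""

    times: np.ndarray
    excursion: np.ndarray  # Hz, >= 0, peak = delta_f
    delta_f: float
    delta_t: float

    @property
    def area(self) -> float:
        """Numerical integral of the excursion (cycles of extra beat phase)."""
        return float(np.trapezoid(self.excursion, self.times))


@dataclass(frozen=True)
class AMWaveform:
    """Sampled amplitude modulation with its generating spec."""

    times: np.ndarray
    values: np.ndarray  # mV/cm
    spec: StimulusSpec
    chirp_onset_time: float | None = None

    @property
    def sample_rate(self) -> float:
        return self.spec.sample_rate


def _excursion_shape(t: np.ndarray, center: float, delta_f: float, delta_t: float) -> np.ndarray:
    sigma = delta_t / 4.0
    u = (np.asarray(t, dtype=float) - center) / sigma
    out = np.zeros_like(u)
    if delta_f == 0:
        return out
    inside = np.abs(u) <= 2.0
    out[inside] = delta_f * (np.exp(-0.5 * u[inside] ** 2) - _EDGE) / (1.0 - _EDGE)
    return out


def chirp_profile_area(delta_f: float, delta_t: float) -> float:
    """Closed-form integral of the excursion profile (beat-phase cycles added).

    Integral of the raised Gaussian over its +-2 sigma support:
    delta_f/(1-e^-2) * (sigma*sqrt(2 pi)*erf(sqrt(2)) - 4 sigma e^-2).
    """
    sigma = delta_t / 4.0
    return (
        delta_f
        / (1.0 - _EDGE)
        * (sigma * np.sqrt(2.0 * np.pi) * float(erf(np.sqrt(2.0))) - 4.0 * sigma * _EDGE)
    )


def make_chirp_profile(
    delta_f: float,
    delta_t: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    center: float | None = None,
) -> ChirpFrequencyProfile:
    """Sampled excursion profile; unimodal, peak ``delta_f``, support ``delta_t``."""
    if delta_t <= 0:
        raise ParameterError(f"delta_t must be > 0, got {delta_t}")
    if delta_f < 0:
        raise ParameterError(f"delta_f must be >= 0, got {delta_f}")
    if center is None:
        center = delta_t / 2.0
    t0 = center - delta_t / 2.0
    n = int(round(delta_t * sample_rate)) + 1
    t = t0 + np.arange(n) / sample_rate
    return ChirpFrequencyProfile(t, _excursion_shape(t, center, delta_f, delta_t), delta_f, delta_t)


def _am_from_cycles(spec: StimulusSpec, t: np.ndarray, cycles: np.ndarray) -> np.ndarray:
    # shared kernel so that insert_chirp with delta_f=0 is bit-identical to make_beat
    return spec.contrast * np.sin(2.0 * np.pi * cycles)


def make_beat(spec: StimulusSpec) -> AMWaveform:
    """Pure sinusoidal beat AM: contrast * sin(2 pi f_beat t)."""
    if spec.chirp_phase is not None:
        raise ParameterError("make_beat requires a beat-only spec (chirp_phase=None)")
    t = spec.time_grid()
    values = _am_from_cycles(spec, t, spec.f_beat * t)
    return AMWaveform(t, values, spec, chirp_onset_time=None)


def excursion_trace(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Chirp excursion (Hz) on an arbitrary time grid; zero for beat-only specs."""
    if spec.chirp_phase is None or spec.delta_f == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    center = spec.chirp_onset_time + spec.delta_t / 2.0
    return _excursion_shape(t, center, spec.delta_f, spec.delta_t)


def insert_chirp(spec: StimulusSpec) -> AMWaveform:
    """Beat AM with the chirp's phase sweep inserted at the requested beat phase.

    Before chirp onset the output equals :func:`make_beat` exactly; afterwards
    the beat is phase-advanced by ``2 pi * integral(excursion) dt``.
    """
    if spec.chirp_phase is None:
        raise ParameterError("insert_chirp requires chirp_phase to be set")
    if spec.chirp_onset_time + spec.delta_t > spec.duration:
        raise ParameterError(
            f"chirp scheduled outside [0, {spec.duration:.4f}] s "
            f"(onset {spec.chirp_onset_time:.4f} s)"
        )
    t = spec.time_grid()
    exc = excursion_trace(spec, t)
    extra_cycles = cumulative_trapezoid(exc, t, initial=0.0)
    values = _am_from_cycles(spec, t, spec.f_beat * t + extra_cycles)
    return AMWaveform(t, values, spec, chirp_onset_time=spec.chirp_onset_time)


def make_waveform(spec: StimulusSpec) -> AMWaveform:
    """Dispatch: beat-only or chirp-bearing waveform depending on the spec."""
    return make_beat(spec) if spec.chirp_phase is None else insert_chirp(spec)


def phase_advance(spec: StimulusSpec) -> float:
    """Permanent beat phase advance caused by the chirp, in radians."""
    return 2.0 * np.pi * chirp_profile_area(spec.delta_f, spec.delta_t)


def phase_grid(spec: StimulusSpec, phases: tuple[float, ...] = PHASE_GRID_DEG) -> list[StimulusSpec]:
    """The 8 specs differing only in chirp phase (0..315 deg in 45 deg steps)."""
    return [replace(spec, chirp_phase=p) for p in phases]
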