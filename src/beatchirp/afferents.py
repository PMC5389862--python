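"""Synthetic peripheral-afferent (P-unit-like) spike-train generator.

The analysis modules assume afferents that (i) follow the stimulus AM with a
high-pass gain, so fast beats drive large rate modulations and *rectification*
(complete firing cessation over part of the beat cycle) at high beat
frequencies, (ii) are stochastic trial to trial, and (iii) are co-modulated
pairwise only through the shared stimulus drive.  The simplest generator with
those properties is a rectified-linear rate model driving an inhomogeneous
Poisson process:

    r(t) = max(0, baseline_rate + g(f_inst(t)) * AM(t)),
    g(f) = gain_at_1hz * f**gain_exponent,

with ``f_inst(t) = f_beat + excursion(t)`` the stimulus's instantaneous
modulation frequency, so chirp responses are strong at every background beat
frequency (the excursion transiently raises the effective modulation frequency
to ~f_beat + delta_f).

Rates are clipped to [0, saturation_rate]: an afferent can neither fire
negatively nor exceed its per-EOD-cycle locking limit, so strong chirp drive
produces synchronized saturation/cessation rather than unbounded rate swings.
The default calibration (baseline 200 Hz, gain 314 (spk/s)/(mV/cm) at 1 Hz,
exponent 0.25, saturation 400 Hz, contrast 0.34 mV/cm) satisfies the two
anchors the analysis relies on: no nonlinearity (neither clip engages) for
beats up to 10 Hz (modulation amplitude 190 Hz at 10 Hz), and a silent
fraction > 25 % of the beat cycle at 64 Hz (analytically 0.27).  The shallow
exponent keeps low-frequency beat responses near the linearity margin, so
single afferents encode the waveform roughly proportionally there while still
rectifying strongly at high beat frequencies.

On top of the envelope-model rate, spiking is phase-locked to the EOD carrier
(a unit-mean von Mises comb at ``eod_frequency``, concentration
``eod_locking_kappa``).  The carrier is common to every afferent, so the comb
is shared drive: it is what gives spike counts measurable co-modulation inside
sub-millisecond correlation bins at high beat frequencies, where the envelope
alone changes too slowly relative to the count shot noise.  The process
remains an inhomogeneous Poisson process (the comb only modulates the rate).

Spikes optionally carry an axonal conduction delay (default 9 ms) so that the
standard 9 ms left-shift applied to neural traces during analysis re-aligns
them with the stimulus, exactly as it does for real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InputError, ParameterError
from .stimulus import AMWaveform, excursion_trace

DEFAULT_BASELINE_RATE = 200.0
DEFAULT_GAIN_AT_1HZ = 314.0
DEFAULT_GAIN_EXPONENT = 0.25
DEFAULT_SATURATION_RATE = 400.0
DEFAULT_AXONAL_DELAY = 0.009
DEFAULT_EOD_FREQUENCY = 823.0
DEFAULT_EOD_LOCKING_KAPPA = 12.0


@dataclass(frozen=True)
class AfferentParams:
    """Rate-model and sampling parameters for one simulated afferent."""

    baseline_rate: float = DEFAULT_BASELINE_RATE  # Hz
    gain_at_1hz: float = DEFAULT_GAIN_AT_1HZ  # (spikes/s) per (mV/cm) at 1 Hz
    gain_exponent: float = DEFAULT_GAIN_EXPONENT  # high-pass power-law slope
    saturation_rate: float | None = DEFAULT_SATURATION_RATE  # Hz ceiling; None = unbounded
    eod_frequency: float = DEFAULT_EOD_FREQUENCY  # Hz, shared carrier the unit locks to
    eod_locking_kappa: float = DEFAULT_EOD_LOCKING_KAPPA  # von Mises concentration; 0 = none
    axonal_delay: float = DEFAULT_AXONAL_DELAY  # s, added to every spike time
    noise_seed: int = 0
    n_trials: int = 200

    def __post_init__(self) -> None:
        if not self.baseline_rate > 0:
            raise ParameterError(f"baseline_rate must be > 0, got {self.baseline_rate}")
        if self.gain_at_1hz < 0:
            raise ParameterError(f"gain_at_1hz must be >= 0, got {self.gain_at_1hz}")
        if self.axonal_delay < 0:
            raise ParameterError(f"axonal_delay must be >= 0, got {self.axonal_delay}")
        if self.n_trials < 1:
            raise ParameterError(f"n_trials must be >= 1, got {self.n_trials}")

    def gain(self, f: np.ndarray | float) -> np.ndarray | float:
        return self.gain_at_1hz * np.asarray(f, dtype=float) ** self.gain_exponent


@dataclass(frozen=True)
class SpikeTrain:
    """Event times of one trial, strictly increasing within [0, duration)."""

    trial_id: int
    spike_times: np.ndarray  # s
    duration: float  # s

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.size and (st[0] < 0 or st[-1] >= self.duration):
            raise InputError("spike times must lie in [0, duration)")
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise InputError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def rate_from_am(am: AMWaveform, params: AfferentParams) -> np.ndarray:
    """Rectified-linear firing rate (Hz) on the AM's time grid.

    Clipped below at zero (rectification) and, when ``saturation_rate`` is
    set, above at the afferent's dynamic-range ceiling (an afferent cannot
    exceed roughly one spike per EOD cycle).  At the default calibration
    neither clip engages for beats up to 10 Hz.
    """
    f_inst = am.spec.f_beat + excursion_trace(am.spec, am.times)
    drive = params.gain(f_inst) * am.values
    r = np.maximum(0.0, params.baseline_rate + drive)
    if params.saturation_rate is not None:
        r = np.minimum(r, params.saturation_rate)
    return r


def silent_fraction_analytic(
    f_beat: float, contrast: float, params: AfferentParams
) -> float:
    """Closed-form fraction of the beat cycle with r = 0 for a pure sine drive.

    With modulation amplitude A = g(f_beat) * contrast, firing stops where
    baseline + A sin(theta) < 0; the silent arc is 0 for A <= baseline and
    pi - 2 arcsin(baseline/A) radians otherwise.
    """
    amp = float(params.gain(f_beat)) * contrast
    if amp <= params.baseline_rate:
        return 0.0
    return 0.5 - float(np.arcsin(params.baseline_rate / amp)) / np.pi


def _locking_comb(t: np.ndarray, params: AfferentParams) -> np.ndarray:
    """Unit-mean von Mises modulation of the rate by the shared EOD carrier.

    P-units fire phase-locked to the EOD cycle; because the carrier is common
    to all afferents, this comb is the shared sub-millisecond drive that
    co-modulates spike counts between units.  kappa = 0 disables locking.
    """
    from scipy.special import i0e

    kappa = params.eod_locking_kappa
    if kappa <= 0:
        return np.ones_like(np.asarray(t, dtype=float))
    theta = 2.0 * np.pi * params.eod_frequency * np.asarray(t, dtype=float)
    # exp(kappa (cos - 1)) / (I0(kappa) e^-kappa): mean over one cycle is 1
    return np.exp(kappa * (np.cos(theta) - 1.0)) / float(i0e(kappa))


def sample_spikes(
    rate: np.ndarray,
    times: np.ndarray,
    params: AfferentParams,
    rng: np.random.Generator | None = None,
) -> list[SpikeTrain]:
    """``n_trials`` inhomogeneous-Poisson realizations of a rate trace.

    The instantaneous rate is the envelope-model rate multiplied by the
    unit-mean EOD locking comb; spikes are drawn by thinning (homogeneous
    candidates at the peak rate, accepted with probability r(t)/r_max), with
    the comb evaluated analytically at candidate times so carrier-scale
    structure is not limited by the envelope grid.  Deterministic for a given
    ``noise_seed``.
    """
    from scipy.special import i0e

    rate = np.asarray(rate, dtype=float)
    times = np.asarray(times, dtype=float)
    if rate.shape != times.shape:
        raise InputError("rate and times must share a grid")
    if np.any(rate < 0):
        raise InputError("rate trace must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(params.noise_seed)
    duration = float(times[-1] - times[0]) + float(times[1] - times[0])
    kappa = params.eod_locking_kappa
    comb_max = 1.0 if kappa <= 0 else 1.0 / float(i0e(kappa))
    r_max = float(rate.max(initial=0.0)) * comb_max
    trains: list[SpikeTrain] = []
    for trial in range(params.n_trials):
        if r_max == 0.0:
            trains.append(SpikeTrain(trial, np.empty(0), duration))
            continue
        n_cand = rng.poisson(r_max * duration)
        cand = np.sort(rng.uniform(times[0], times[0] + duration, size=n_cand))
        r_cand = np.interp(cand, times, rate) * _locking_comb(cand, params)
        accept = rng.uniform(0.0, r_max, size=n_cand) < r_cand
        spikes = cand[accept] + params.axonal_delay
        spikes = spikes[spikes < duration]
        spikes = np.unique(spikes)  # strictly increasing (ties have measure zero)
        trains.append(SpikeTrain(trial, spikes, duration))
    return trains


def simulate_afferent(am: AMWaveform, params: AfferentParams) -> list[SpikeTrain]:
    """Rate model + Poisson sampling for one afferent."""
    return sample_spikes(rate_from_am(am, params), am.times, params)


def make_population(
    am: AMWaveform, params_list: list[AfferentParams]
) -> list[list[SpikeTrain]]:
    """Simulate several afferents driven by the *same* AM (shared drive) with
    independent private noise.  Returns one trial list per afferent."""
    if len(params_list) < 2:
        raise ConfigurationError(
            f"pairwise correlation analyses need >= 2 afferents, got {len(params_list)}"
        )
    n_trials = {p.n_trials for p in params_list}
    if len(n_trials) != 1:
        raise ConfigurationError("all afferents must use the same n_trials")
    return [simulate_afferent(am, p) for p in params_list]


def default_pair(seed: int, n_trials: int = 200) -> list[AfferentParams]:
    """Two default-calibration afferents with independent seeds."""
    base = AfferentParams(n_trials=n_trials)
    return [
        replace(base, noise_seed=seed),
        replace(base, noise_seed=seed + 1_000_003),
    ]
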