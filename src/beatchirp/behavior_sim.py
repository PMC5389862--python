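"""Synthetic echo-chirp behavior generator.

Weakly electric fish tend to answer a received chirp with a chirp of their own
within about a second (the *echo response*); its rate is the behavioral
readout of chirp detectability.  The generator models emission as a driven
point process, not a sensorimotor mechanism: a homogeneous baseline emission
rate plus, after each stimulus chirp, a latency-jittered transient whose
integrated area is ``echo_gain * drive`` emitted chirps, with ``drive`` in
[0, 1] a detectability value supplied per (beat frequency, phase) condition.
By default the pipeline feeds it the correlation-based neuronal detectability,
implementing the hypothesis that correlated afferent activity is what
downstream decoders read out -- a model choice, not an observation.

Emitted-chirp characteristics (frequency excursion, duration) are drawn from
a single beat-frequency-independent distribution (60-150 Hz, 10-20 ms), so a
Kruskal-Wallis test across beat frequencies is null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

DEFAULT_BASELINE_EMISSION_RATE = 0.05  # chirps/s
DEFAULT_ECHO_GAIN = 2.0  # mean echoes per stimulus chirp at drive = 1
DEFAULT_LATENCY_MEAN = 0.35  # s
DEFAULT_LATENCY_SD = 0.15  # s
DEFAULT_ECHO_TRIALS = 1000

#: support of emitted small-chirp characteristics, beat-frequency independent
CHIRP_DELTA_F_RANGE = (60.0, 150.0)  # Hz
CHIRP_DELTA_T_RANGE = (0.010, 0.020)  # s


@dataclass(frozen=True)
class EchoParams:
    baseline_emission_rate: float = DEFAULT_BASELINE_EMISSION_RATE
    echo_gain: float = DEFAULT_ECHO_GAIN
    latency_mean: float = DEFAULT_LATENCY_MEAN
    latency_sd: float = DEFAULT_LATENCY_SD
    n_trials: int = DEFAULT_ECHO_TRIALS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_emission_rate < 0:
            raise ParameterError(
                f"baseline_emission_rate must be >= 0, got {self.baseline_emission_rate}"
            )
        if self.echo_gain < 0:
            raise ParameterError(f"echo_gain must be >= 0, got {self.echo_gain}")
        if self.n_trials < 1:
            raise ParameterError(f"n_trials must be >= 1, got {self.n_trials}")


@dataclass(frozen=True)
class EchoSeries:
    """One trial: stimulus chirp times and the fish's emitted chirp times."""

    trial_id: int
    stimulus_chirp_times: np.ndarray  # s
    emitted_chirp_times: np.ndarray  # s, within [0, duration)
    duration: float
    f_beat: float
    phase: float


def _truncated_latencies(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal latencies truncated by rejection to (0, 1) s, preserving count."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        draw = draw[(draw > 0.0) & (draw < 1.0)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_echoes(
    stimulus_chirp_times: np.ndarray,
    trial_duration: float,
    drive: float,
    params: EchoParams,
    f_beat: float,
    phase: float,
    rng: np.random.Generator | None = None,
) -> list[EchoSeries]:
    """Inhomogeneous emission process: baseline + post-chirp transient.

    Per stimulus chirp the number of echo emissions is Poisson with mean
    ``echo_gain * drive`` and each echo occurs at onset + latency (truncated
    normal within the 1 s response window).  Reproducible under seed.
    """
    if not 0.0 <= drive <= 1.0:
        raise InputError(f"drive must lie in [0, 1], got {drive}")
    stimulus_chirp_times = np.asarray(stimulus_chirp_times, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    series: list[EchoSeries] = []
    for trial in range(params.n_trials):
        n_base = rng.poisson(params.baseline_emission_rate * trial_duration)
        emitted = [rng.uniform(0.0, trial_duration, size=n_base)]
        for onset in stimulus_chirp_times:
            n_echo = rng.poisson(params.echo_gain * drive)
            if n_echo:
                emitted.append(onset + _truncated_latencies(
                    rng, n_echo, params.latency_mean, params.latency_sd))
        times = np.concatenate(emitted)
        times = np.sort(times[times < trial_duration])
        series.append(EchoSeries(trial, stimulus_chirp_times, times, trial_duration, f_beat, phase))
    return series


def emitted_chirp_stats(series_set: list[EchoSeries], seed: int = 0) -> pd.DataFrame:
    """Per-emitted-chirp characteristics, drawn from one f_beat-independent
    distribution: delta_f ~ U(60, 150) Hz, delta_t ~ U(10, 20) ms."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in series_set:
        for t in s.emitted_chirp_times:
            rows.append(
                {
                    "trial_id": s.trial_id,
                    "f_beat": s.f_beat,
                    "phase": s.phase,
                    "time_s": float(t),
                    "delta_f_hz": rng.uniform(*CHIRP_DELTA_F_RANGE),
                    "delta_t_s": rng.uniform(*CHIRP_DELTA_T_RANGE),
                }
            )
    return pd.DataFrame(
        rows, columns=["trial_id", "f_beat", "phase", "time_s", "delta_f_hz", "delta_t_s"]
    )
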