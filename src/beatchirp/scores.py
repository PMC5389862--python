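"""Distance, detectability, invariance, and response-duration power laws.

The central measure is the normalized distance between two traces x, y over an
analysis window:

    D(x, y) = <(x - <x> - y + <y>)^2> / max[(max x - min x)/2, (max y - min y)/2]

with <.> the window average.  D is zero iff the traces are identical up to a
constant offset.  Built on it are

* stimulus detectability: D between the chirp-bearing AM and the phase-matched
  unperturbed beat over one full beat cycle after chirp onset;
* inter-chirp distance: mean D over all unordered pairs of the 8 phase
  variants, over the 14 ms chirp window;
* neuronal detectability: |R_chirp - R_beat| / (R_chirp + R_beat) with
  R = max - min of the response in its window (chirp window from the
  response-duration power-law fit, beat window one beat cycle);
* the invariance score I = 1 - meanD(responses) / meanD(stimuli), clipped to
  [0, 1]: 1 when responses to the same chirp at all 8 beat phases are
  identical, ~0 when responses are as dissimilar as the stimulus waveforms
  themselves.

Because D is linear (not scale-free) in trace amplitude, each trace *set*
entering the invariance ratio is first rescaled by its own maximum half
peak-to-peak range inside the window, so the response/stimulus ratio does not
depend on physical units (Hz vs. mV/cm vs. dimensionless rho).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import Trace
from .errors import InputError, UndefinedMetricError

DEFAULT_DURATION_THRESHOLD_K = 2.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open window [start, start + length) on a trace's time axis."""

    start: float
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InputError(f"window length must be > 0, got {self.length}")

    @property
    def stop(self) -> float:
        return self.start + self.length


@dataclass(frozen=True)
class DurationFit:
    """Power law d = a * f**b through per-frequency response durations."""

    a: float
    b: float
    r_squared: float
    f_beats: np.ndarray
    durations: np.ndarray  # s; NaN where undefined (excluded from the fit)

    def window_at(self, f_beat: float) -> float:
        return float(self.a * f_beat**self.b)


def _window_values(trace: Trace, window: AnalysisWindow) -> np.ndarray:
    m = (trace.times >= window.start) & (trace.times < window.stop)
    v = trace.values[m]
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise InputError(f"no defined samples in window [{window.start}, {window.stop})")
    return v


def distance(x: Trace, y: Trace, window: AnalysisWindow) -> float:
    """Normalized mean-squared distance D(x, y) over the window.

    Requires a shared grid inside the window.  Samples where either trace is
    undefined (NaN, e.g. zero-variance correlation windows) are excluded
    pairwise.  Undefined (raises) when both traces are constant there.
    """
    mx = (x.times >= window.start) & (x.times < window.stop)
    my = (y.times >= window.start) & (y.times < window.stop)
    if mx.sum() != my.sum():
        raise InputError(
            "traces must share a grid over the window "
            f"({int(mx.sum())} vs {int(my.sum())} samples); resample first"
        )
    xs, ys = x.values[mx], y.values[my]
    ok = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[ok], ys[ok]
    if xs.size == 0:
        raise InputError(f"no jointly defined samples in window [{window.start}, {window.stop})")
    # <(x - <x> - y + <y>)^2> computed as the variance of (x - y): algebraically
    # identical, and exactly zero for traces equal up to a constant offset
    d = xs - ys
    num = float(np.mean((d - d.mean()) ** 2))
    denom = max(float(np.ptp(xs)), float(np.ptp(ys))) / 2.0
    if denom == 0.0:
        raise UndefinedMetricError("distance undefined: both traces constant in window")
    return num / denom


def mean_pairwise_distance(traces: list[Trace], window: AnalysisWindow) -> float:
    """Mean D over all unordered pairs (28 pairs for the 8-phase set)."""
    if len(traces) < 2:
        raise InputError(f"need >= 2 traces, got {len(traces)}")
    return float(
        np.mean([distance(a, b, window) for a, b in combinations(traces, 2)])
    )


def _normalized_set(traces: list[Trace], window: AnalysisWindow) -> list[Trace]:
    scale = max(np.ptp(_window_values(tr, window)) for tr in traces) / 2.0
    if scale == 0.0:
        return traces
    return [Trace(tr.times, tr.values / scale) for tr in traces]


def stimulus_detectability(chirp_am: Trace, beat_am: Trace, f_beat: float, chirp_onset: float) -> float:
    """D between chirp waveform and phase-matched unperturbed beat over one
    full beat cycle after chirp onset.  0 iff the chirp leaves the beat
    unchanged; larger when the perturbation stands out from the background."""
    window = AnalysisWindow(chirp_onset, 1.0 / f_beat)
    return distance(chirp_am, beat_am, window)


def inter_chirp_distance(aligned_waveforms: list[Trace], chirp_duration: float) -> float:
    """Mean pairwise D among phase variants, on chirp-onset-aligned traces,
    over the chirp-duration window after onset (t = 0)."""
    if len(aligned_waveforms) < 2:
        raise InputError("need >= 2 waveforms for inter-chirp distance")
    return mean_pairwise_distance(aligned_waveforms, AnalysisWindow(0.0, chirp_duration))


def response_range(trace: Trace, window: AnalysisWindow) -> float:
    """R = max - min of the response within the window."""
    return float(np.ptp(_window_values(trace, window)))


def neuronal_detectability(
    resp_chirp: Trace,
    resp_beat: Trace,
    chirp_window: AnalysisWindow,
    beat_window: AnalysisWindow,
) -> float:
    """|R_chirp - R_beat| / (R_chirp + R_beat), in [0, 1].

    Applies identically to PSTHs and correlation time courses.  Undefined when
    both ranges vanish.
    """
    r_chirp = response_range(resp_chirp, chirp_window)
    r_beat = response_range(resp_beat, beat_window)
    if r_chirp + r_beat == 0.0:
        raise UndefinedMetricError("neuronal detectability undefined: both ranges zero")
    return abs(r_chirp - r_beat) / (r_chirp + r_beat)


def invariance_score(
    responses: list[Trace],
    stimuli: list[Trace],
    response_window: AnalysisWindow,
    stimulus_window: AnalysisWindow | None = None,
) -> float:
    """I = 1 - meanD(responses) / meanD(stimuli), clipped to [0, 1].

    Responses and stimuli must each be chirp-onset-aligned sets (one trace per
    beat phase).  Each set is normalized by its own maximum half peak-to-peak
    range in its window before the pairwise distances, making the ratio
    unit-free.  Undefined when the stimuli are mutually identical.
    """
    if stimulus_window is None:
        stimulus_window = response_window
    if len(responses) != len(stimuli):
        raise InputError("need one response per stimulus phase variant")
    resp_n = _normalized_set(responses, response_window)
    stim_n = _normalized_set(stimuli, stimulus_window)
    d_stim = mean_pairwise_distance(stim_n, stimulus_window)
    if d_stim == 0.0:
        raise UndefinedMetricError("invariance undefined: zero mean stimulus distance")
    try:
        d_resp = mean_pairwise_distance(resp_n, response_window)
    except UndefinedMetricError:
        # all responses constant in the window: mutually identical up to offsets
        d_resp = 0.0
    return float(np.clip(1.0 - d_resp / d_stim, 0.0, 1.0))


def _nan_boxcar(x: np.ndarray, n: int) -> np.ndarray:
    """Boxcar smoothing that ignores NaN samples (normalizes by valid count)."""
    if n <= 1:
        return x
    from scipy.ndimage import uniform_filter1d

    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)
    num = uniform_filter1d(filled, n, mode="reflect")
    den = uniform_filter1d(valid.astype(float), n, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def response_duration(
    resp_chirp: Trace,
    resp_reference: Trace,
    onset: float,
    beat_epoch: tuple[float, float],
    k: float = DEFAULT_DURATION_THRESHOLD_K,
    smooth: float = 0.0,
    max_gap: float = 0.0,
    max_duration: float | None = None,
) -> float:
    """Length (s) of the contiguous post-onset interval where the response
    deviates from its no-chirp reference.

    The deviation |resp_chirp - resp_reference| (optionally boxcar-smoothed
    over ``smooth`` seconds, so the oscillatory deviation is measured by its
    envelope rather than terminated at every zero crossing) is compared
    against mean + k * SD of the same smoothed deviation over the beat epoch
    (pre-chirp baseline noise).  Sub-threshold gaps shorter than ``max_gap``
    seconds do not terminate the interval (contiguity at the envelope
    resolution); ``max_duration`` caps the result.  Returns NaN when no
    suprathreshold interval exists.
    """
    if resp_chirp.times.size != resp_reference.times.size or not np.allclose(
        resp_chirp.times, resp_reference.times
    ):
        raise InputError("chirp response and reference must share a time grid")
    diff = np.abs(resp_chirp.values - resp_reference.values)
    t = resp_chirp.times
    if smooth > 0:
        dt_s = float(t[1] - t[0])
        diff = _nan_boxcar(diff, max(1, int(round(smooth / dt_s))))
    epoch = (t >= beat_epoch[0]) & (t < beat_epoch[1])
    if not np.any(epoch):
        raise InputError("empty beat epoch")
    base = diff[epoch]
    if np.all(np.isnan(base)):
        raise InputError("beat epoch entirely undefined")
    threshold = float(np.nanmean(base) + k * np.nanstd(base))
    post = t >= onset
    above = diff[post] > threshold  # NaN deviations compare False
    if not np.any(above):
        return float("nan")
    dt = float(t[1] - t[0])
    gap_bins = int(np.floor(max_gap / dt))
    idx = np.flatnonzero(above)
    first = idx[0]
    run_end = first
    for i in idx[1:]:
        if i - run_end - 1 > gap_bins:
            break
        run_end = i
    duration = (run_end - first + 1) * dt
    if max_duration is not None:
        duration = min(duration, max_duration)
    return duration


def fit_duration_powerlaw(f_beats: np.ndarray, durations: np.ndarray) -> DurationFit:
    """Least-squares power law in log-log coordinates, with R^2.

    NaN durations (no suprathreshold response at that frequency) are excluded;
    at least 3 valid frequencies are required.
    """
    f_beats = np.asarray(f_beats, dtype=float)
    durations = np.asarray(durations, dtype=float)
    valid = np.isfinite(durations) & (durations > 0)
    if valid.sum() < 3:
        raise InputError(f"need >= 3 valid frequencies to fit, got {int(valid.sum())}")
    lx, ly = np.log10(f_beats[valid]), np.log10(durations[valid])
    b, log_a = np.polyfit(lx, ly, 1)
    resid = ly - (log_a + b * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DurationFit(10.0**log_a, float(b), r2, f_beats, durations)
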