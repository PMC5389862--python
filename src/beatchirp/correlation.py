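"""Time-resolved pairwise spike-count correlation over beat-scaled windows.

For a beat at ``f_beat`` the correlation window length is 12.5 % of the beat
period, ``T = 0.125 / f_beat`` (125 ms at 1 Hz down to 0.98 ms at 128 Hz), so
the estimator keeps a fixed resolution in beat-cycle units as the chirp
response shrinks with increasing beat frequency.  Each window is discretized
into 5 bins; at every window position the per-trial, per-bin spike counts of
the two afferents form the paired sample whose Pearson correlation

    rho(n_i, n_j) = Cov(n_i, n_j) / sqrt(Var(n_i) Var(n_j))

is reported.  The window slides in steps of ``0.001 / f_beat`` seconds (0.1 %
of the beat period); since one window bin spans exactly 25 slide steps, counts
are accumulated once on the slide-step micro-grid and window-bin counts are
recovered from cumulative sums, which makes the full trace a handful of
vectorized passes.

Windows where either count series has zero variance (e.g. mutual silence)
yield an *undefined* correlation, carried as NaN and excluded from downstream
averages -- never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afferents import SpikeTrain
from .core import Trace
from .errors import InputError, ParameterError

DEFAULT_WINDOW_FRACTION = 0.125  # of the beat period
DEFAULT_BINS_PER_WINDOW = 5
DEFAULT_SLIDE_FRACTION = 0.001  # of the beat period


@dataclass(frozen=True)
class CorrelationTrace:
    """rho vs. time (window centers); NaN marks undefined windows."""

    times: np.ndarray
    rho: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rho)

    def as_trace(self) -> Trace:
        return Trace(self.times, self.rho)


def window_length(f_beat: float, window_fraction: float = DEFAULT_WINDOW_FRACTION) -> float:
    """Correlation window length T = 12.5 % of the beat period, in seconds."""
    if f_beat <= 0:
        raise ParameterError(f"f_beat must be > 0, got {f_beat}")
    return window_fraction / f_beat


def _count_matrix(trains: list[SpikeTrain], micro: float, n_micro: int) -> np.ndarray:
    # int32 keeps the cumulative counts exact (< 2^31 spikes) at half the
    # memory traffic of int64; the hot loop below is bandwidth-bound
    out = np.zeros((len(trains), n_micro + 1), dtype=np.int32)
    for row, tr in enumerate(trains):
        idx = np.floor(tr.spike_times / micro).astype(int)
        idx = idx[idx < n_micro]
        out[row, 1:] = np.bincount(idx, minlength=n_micro)
    return np.cumsum(out, axis=1, dtype=np.int32)


def sliding_correlation(
    trains_i: list[SpikeTrain],
    trains_j: list[SpikeTrain],
    f_beat: float,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    bins_per_window: int = DEFAULT_BINS_PER_WINDOW,
    slide_fraction: float = DEFAULT_SLIDE_FRACTION,
    per_trial: bool = False,
) -> CorrelationTrace:
    """Pearson correlation of windowed spike counts as a function of time.

    The paired sample at each window position pools the ``bins_per_window``
    counts of every trial (the pooled reading of "series of spike counts").
    ``per_trial=True`` (correlate within trials, then average) is reserved as
    an alternative reading and not implemented.
    """
    if per_trial:
        raise NotImplementedError(
            "per-trial-then-average correlation is a config stub; "
            "only the pooled estimator is implemented"
        )
    if f_beat <= 0:
        raise ParameterError(f"f_beat must be > 0, got {f_beat}")
    if len(trains_i) != len(trains_j) or not trains_i:
        raise InputError("both afferents need the same, nonzero number of trials")
    duration = min(min(t.duration for t in trains_i), min(t.duration for t in trains_j))

    micro = slide_fraction / f_beat
    m = window_fraction / (bins_per_window * slide_fraction)
    if abs(m - round(m)) > 1e-9:
        raise ParameterError(
            "window_fraction must be an integer multiple of "
            "bins_per_window * slide_fraction"
        )
    m = int(round(m))  # micro-bins per window bin
    n_micro = int(np.floor(duration / micro))
    win_micro = m * bins_per_window
    n_pos = n_micro - win_micro + 1
    if n_pos < 1:
        raise InputError("trains shorter than one correlation window")

    cs_i = _count_matrix(trains_i, micro, n_micro)
    cs_j = _count_matrix(trains_j, micro, n_micro)

    n_trials = len(trains_i)
    n_samples = n_trials * bins_per_window
    # all sufficient statistics are integer-valued and accumulated exactly
    sum_i = np.zeros(n_pos, dtype=np.int64)
    sum_j = np.zeros(n_pos, dtype=np.int64)
    sq_i = np.zeros(n_pos, dtype=np.int64)
    sq_j = np.zeros(n_pos, dtype=np.int64)
    cross = np.zeros(n_pos, dtype=np.int64)
    for k in range(bins_per_window):
        lo, hi = k * m, (k + 1) * m
        d_i = cs_i[:, hi : hi + n_pos] - cs_i[:, lo : lo + n_pos]
        d_j = cs_j[:, hi : hi + n_pos] - cs_j[:, lo : lo + n_pos]
        sum_i += d_i.sum(axis=0, dtype=np.int64)
        sum_j += d_j.sum(axis=0, dtype=np.int64)
        sq_i += (d_i * d_i).sum(axis=0, dtype=np.int64)
        sq_j += (d_j * d_j).sum(axis=0, dtype=np.int64)
        cross += (d_i * d_j).sum(axis=0, dtype=np.int64)

    mean_i = sum_i / n_samples
    mean_j = sum_j / n_samples
    var_i = sq_i / n_samples - mean_i**2
    var_j = sq_j / n_samples - mean_j**2
    cov = cross / n_samples - mean_i * mean_j
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(var_i * var_j)
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    rho = np.clip(rho, -1.0, 1.0)  # numerical guard; NaN propagates

    centers = (np.arange(n_pos) + win_micro / 2.0) * micro
    return CorrelationTrace(centers, rho)


def correlation_chirp_alignment(
    trace: CorrelationTrace, chirp_onset: float | None
) -> CorrelationTrace:
    """Re-zero the time axis at chirp onset (no-op for beat-only traces)."""
    if chirp_onset is None:
        return trace
    if not (trace.times[0] <= chirp_onset <= trace.times[-1]):
        raise InputError("chirp onset outside correlation trace span")
    return CorrelationTrace(trace.times - chirp_onset, trace.rho)
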