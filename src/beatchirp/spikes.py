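"""Single-train metrics: binary sequences, PSTHs, phase histograms, phase locking.

The phase-locking index used here is deliberately *not* vector strength: it is
the fraction of phase-histogram bins whose count falls below a small threshold
(a fixed fraction of the mean bin count), so it responds only to genuine
firing cessation (rectification) over part of the beat cycle, not to smooth
sinusoidal rate modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .afferents import SpikeTrain
from .core import Trace
from .errors import InputError, ParameterError, UndefinedMetricError

DEFAULT_BINARY_BINWIDTH = 0.0005  # s
DEFAULT_PSTH_BINWIDTH = 0.0001  # s
DEFAULT_PSTH_SMOOTH = 0.006  # s, boxcar length
DEFAULT_PHASE_BINS = 20
#: threshold on phase-histogram bins, as a fraction of the mean bin count
DEFAULT_PLI_THRESHOLD_FACTOR = 0.0005
#: left shift applied to neural (never stimulus or behavioral) traces, s
DEFAULT_NEURAL_DELAY = 0.009


@dataclass(frozen=True)
class BinarySequence:
    """Spike counts in contiguous half-open bins [k*w, (k+1)*w)."""

    counts: np.ndarray  # nonnegative ints
    binwidth: float  # s

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged smoothed firing rate."""

    times: np.ndarray  # bin centers, s
    rate: np.ndarray  # Hz
    binwidth: float
    smooth_width: float
    n_trials: int

    def as_trace(self) -> Trace:
        return Trace(self.times, self.rate)


@dataclass(frozen=True)
class PhaseHistogram:
    """Spike counts over beat phase, bins tiling [0, 360) degrees."""

    counts: np.ndarray
    n_bins: int

    @property
    def bin_edges_deg(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.n_bins + 1)


def binarize(train: SpikeTrain, binwidth: float = DEFAULT_BINARY_BINWIDTH) -> BinarySequence:
    """Bin spike times; a spike at t lands in bin floor(t/binwidth)."""
    if binwidth <= 0:
        raise ParameterError(f"binwidth must be > 0, got {binwidth}")
    n_bins = int(np.ceil(train.duration / binwidth))
    idx = np.floor(train.spike_times / binwidth).astype(int)
    counts = np.bincount(idx, minlength=max(n_bins, 1))
    return BinarySequence(counts, binwidth)


def _odd_kernel_bins(smooth_width: float, binwidth: float) -> int:
    n = max(1, int(round(smooth_width / binwidth)))
    return n + 1 if n % 2 == 0 else n


def psth(
    trains: list[SpikeTrain],
    binwidth: float = DEFAULT_PSTH_BINWIDTH,
    smooth_width: float = DEFAULT_PSTH_SMOOTH,
) -> PSTH:
    """Trial-averaged rate, smoothed with a boxcar filter.

    Edge handling is reflect padding, which conserves the PSTH integral (mean
    spike count per trial) exactly, so no rate is lost at window edges aligned
    to chirp onset.  The boxcar length is rounded to an odd number of bins.
    """
    if not trains:
        raise InputError("psth needs at least one trial")
    duration = trains[0].duration
    edges = np.arange(0.0, duration + binwidth, binwidth)
    counts = np.zeros(edges.size - 1)
    for tr in trains:
        c, _ = np.histogram(tr.spike_times, bins=edges)
        counts += c
    rate = counts / (len(trains) * binwidth)
    if smooth_width > 0:
        rate = uniform_filter1d(rate, _odd_kernel_bins(smooth_width, binwidth), mode="reflect")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PSTH(centers, rate, binwidth, smooth_width, len(trains))


def phase_histogram(
    trains: list[SpikeTrain] | SpikeTrain,
    f_beat: float,
    phase0: float = 0.0,
    n_bins: int = DEFAULT_PHASE_BINS,
    t_stop: float | None = None,
) -> PhaseHistogram:
    """Histogram of spike beat-phases ``(2 pi f_beat t + phase0) mod 2 pi``.

    Only spikes from the beat epoch (t < t_stop, e.g. before chirp onset) are
    included; ``t_stop=None`` uses the whole train.
    """
    if f_beat <= 0:
        raise ParameterError(f"f_beat must be > 0, got {f_beat}")
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    if t_stop is not None and t_stop <= 0:
        raise InputError("no beat epoch: t_stop must be > 0")
    all_phases = []
    for tr in trains:
        t = tr.spike_times
        if t_stop is not None:
            t = t[t < t_stop]
        all_phases.append((2.0 * np.pi * f_beat * t + phase0) % (2.0 * np.pi))
    phases = np.concatenate(all_phases) if all_phases else np.empty(0)
    counts, _ = np.histogram(phases, bins=n_bins, range=(0.0, 2.0 * np.pi))
    return PhaseHistogram(counts, n_bins)


def phase_locking_index(
    hist: PhaseHistogram, threshold_factor: float = DEFAULT_PLI_THRESHOLD_FACTOR
) -> float:
    """Fraction of phase-histogram bins below ``threshold_factor * mean count``.

    0 for spikes spread over all phases; approaches (n_bins-1)/n_bins when all
    spikes share one phase.  With count data and the default factor this
    effectively counts exactly-silent bins.  Undefined for an empty histogram.
    """
    if hist.n_bins < 2:
        raise ParameterError(f"need >= 2 bins, got {hist.n_bins}")
    total = hist.counts.sum()
    if total == 0:
        raise UndefinedMetricError("phase-locking index undefined for an empty histogram")
    threshold = threshold_factor * total / hist.n_bins
    return float(np.count_nonzero(hist.counts < threshold) / hist.n_bins)


def shift_response(trace: Trace, delay: float = DEFAULT_NEURAL_DELAY) -> Trace:
    """Advance a neural trace's time axis by ``delay`` (t -> t - delay).

    Compensates known axonal transmission delays so neural responses align
    with the stimulus; never applied to stimulus or behavioral traces.
    """
    if abs(delay) > trace.span:
        raise InputError(f"delay {delay} s exceeds trace span {trace.span} s")
    return trace.shifted(delay)
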