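"""Echo-response quantification: chirp rate, behavioral PSTHs, invariance,
and block-bootstrap standard errors.

All behavioral measures use a fixed 1 s window after stimulus chirp onset:
the chirp rate is the mean emitted-chirp count in that window divided by its
length, and behavioral PSTHs resolve the same window into 10 ms bins.
Behavioral invariance reuses the neural invariance score with behavioral
PSTHs as responses.  Uncertainty is estimated with a moving-block bootstrap
(block size 31) so serial dependence in chirp emission inflates the standard
error as it should.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .behavior_sim import EchoSeries
from .core import Trace
from .errors import InputError
from .scores import AnalysisWindow, invariance_score

DEFAULT_RESPONSE_WINDOW = 1.0  # s after stimulus chirp onset
DEFAULT_BEHAVIOR_BINWIDTH = 0.010  # s
DEFAULT_BEHAVIOR_SMOOTH = 0.050  # s boxcar; chirp emissions are sparse events
DEFAULT_BLOCK_SIZE = 31


def per_chirp_counts(series_set: Sequence[EchoSeries], window: float = DEFAULT_RESPONSE_WINDOW) -> np.ndarray:
    """Emitted-chirp count in (onset, onset + window] for every stimulus chirp
    of every trial, in presentation order (the series the bootstrap resamples)."""
    counts = []
    for s in series_set:
        for onset in s.stimulus_chirp_times:
            counts.append(
                int(np.count_nonzero(
                    (s.emitted_chirp_times > onset) & (s.emitted_chirp_times <= onset + window)
                ))
            )
    if not counts:
        raise InputError("no stimulus chirps in series set")
    return np.asarray(counts, dtype=float)


def chirp_rate(series_set: Sequence[EchoSeries], window: float = DEFAULT_RESPONSE_WINDOW) -> float:
    """Mean emitted chirps per second in the response window, averaged over
    stimulus chirps and trials."""
    return float(per_chirp_counts(series_set, window).mean() / window)


def behavioral_psth(
    series_set: Sequence[EchoSeries],
    binwidth: float = DEFAULT_BEHAVIOR_BINWIDTH,
    window: float = DEFAULT_RESPONSE_WINDOW,
    smooth: float = DEFAULT_BEHAVIOR_SMOOTH,
) -> Trace:
    """Rate of emitted chirps vs. time from stimulus chirp onset (Hz).

    Chirp emissions are sparse, so the binned rate is boxcar-smoothed over
    ``smooth`` seconds (integral-conserving reflect padding); pass 0 for the
    raw histogram.
    """
    edges = np.arange(0.0, window + binwidth, binwidth)
    counts = np.zeros(edges.size - 1)
    n_chirps = 0
    for s in series_set:
        for onset in s.stimulus_chirp_times:
            rel = s.emitted_chirp_times - onset
            c, _ = np.histogram(rel[(rel > 0) & (rel <= window)], bins=edges)
            counts += c
            n_chirps += 1
    if n_chirps == 0:
        raise InputError("no stimulus chirps in series set")
    centers = 0.5 * (edges[:-1] + edges[1:])
    rate = counts / (n_chirps * binwidth)
    rate = _smooth_rate(rate, smooth, binwidth)
    return Trace(centers, rate)


def _smooth_rate(rate: np.ndarray, smooth: float, binwidth: float) -> np.ndarray:
    if smooth <= 0:
        return rate
    from scipy.ndimage import uniform_filter1d

    n = max(1, int(round(smooth / binwidth)))
    n = n + 1 if n % 2 == 0 else n
    return uniform_filter1d(rate, n, mode="reflect")


def behavioral_invariance(
    psths: list[Trace],
    stimuli: list[Trace],
    window: float = DEFAULT_RESPONSE_WINDOW,
) -> float:
    """Invariance score with behavioral PSTHs as responses over the 1 s window.

    ``stimuli`` are the chirp-onset-aligned AM waveforms of the same 8 phase
    conditions, windowed over the same 1 s.
    """
    return invariance_score(psths, stimuli, AnalysisWindow(0.0, window))


def block_bootstrap(
    series: np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Moving-block bootstrap SE and 95 % percentile CI of a statistic.

    Contiguous blocks of ``block_size`` are resampled with replacement and
    concatenated to the original length; the statistic is recomputed per
    replicate and the SE is the SD over replicates.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < block_size:
        raise InputError(f"series of length {n} shorter than one block ({block_size})")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_size))
    starts = rng.integers(0, n - block_size + 1, size=(n_boot, n_blocks))
    idx = (starts[:, :, None] + np.arange(block_size)[None, None, :]).reshape(n_boot, -1)[:, :n]
    reps = np.apply_along_axis(statistic, 1, series[idx])
    se = float(np.std(reps, ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return se, (float(lo), float(hi))
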