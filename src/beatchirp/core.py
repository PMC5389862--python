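"""Lightweight time-series container used by every analysis module.

All neural and behavioral analyses in this package operate on uniformly
sampled traces (rate vs. time, correlation vs. time, amplitude vs. time).
:class:`Trace` keeps the time axis explicit so that chirp-onset alignment and
the 9 ms axonal-delay shift are ordinary, testable operations on data rather
than bookkeeping conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class Trace:
    """A sampled time series: ``values[i]`` observed at ``times[i]`` (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise InputError("times and values must be 1-D arrays of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise InputError("trace too short to define a sampling step")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def crop(self, start: float, stop: float) -> "Trace":
        """Return the sub-trace with ``start <= t < stop``."""
        m = (self.times >= start) & (self.times < stop)
        if not np.any(m):
            raise InputError(f"empty crop window [{start}, {stop})")
        return Trace(self.times[m], self.values[m])

    def shifted(self, delay: float) -> "Trace":
        """Advance the time axis by ``delay`` seconds (t -> t - delay)."""
        return replace(self, times=self.times - delay)

    def interp(self, new_times: np.ndarray) -> "Trace":
        """Linear resampling onto ``new_times`` (used to put traces with
        different native grids on a common index set)."""
        new_times = np.asarray(new_times, dtype=float)
        return Trace(new_times, np.interp(new_times, self.times, self.values))


def common_grid(traces: list[Trace], start: float, stop: float) -> list[Trace]:
    """Resample traces onto the coarsest grid among them over [start, stop)."""
    if not traces:
        raise InputError("no traces given")
    dt = max(tr.dt for tr in traces)
    grid = np.arange(start, stop, dt)
    if grid.size == 0:
        raise InputError("empty common grid")
    return [tr.interp(grid) for tr in traces]
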