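"""Run configuration for the full experiment grid (beat frequencies x phases)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

from .afferents import AfferentParams
from .behavior_sim import EchoParams
from .errors import ConfigurationError
from .io import load_yaml
from .stimulus import PHASE_GRID_DEG

#: beat frequencies of the standard stimulus set, Hz
DEFAULT_FREQUENCIES = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


@dataclass(frozen=True)
class AnalysisKnobs:
    """Analysis parameters; defaults follow the standard recipe."""

    window_fraction: float = 0.125  # correlation window, fraction of beat period
    bins_per_window: int = 5
    slide_fraction: float = 0.001  # window slide step, fraction of beat period
    neural_delay: float = 0.009  # s, left shift of neural traces
    duration_threshold_k: float = 2.0  # SDs over beat-epoch noise
    pli_threshold_factor: float = 0.0005  # of mean phase-histogram count
    phase_bins: int = 20
    psth_binwidth: float = 0.0001  # s
    psth_smooth: float = 0.006  # s
    behavior_binwidth: float = 0.010  # s
    behavior_smooth: float = 0.050  # s boxcar on behavioral PSTHs
    behavior_window: float = 1.0  # s
    bootstrap_block: int = 31
    bootstrap_reps: int = 500


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    phases: tuple[float, ...] = PHASE_GRID_DEG
    delta_f: float = 60.0
    delta_t: float = 0.014
    contrast: float = 0.34
    sample_rate: float = 10_000.0
    n_afferents: int = 4  # population size; rho is averaged over all pairs
    afferent: AfferentParams = field(default_factory=AfferentParams)
    echo: EchoParams = field(default_factory=EchoParams)
    analysis: AnalysisKnobs = field(default_factory=AnalysisKnobs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ConfigurationError("frequencies must be non-empty")
        if any(f <= 0 for f in self.frequencies):
            raise ConfigurationError("beat frequencies must be > 0")
        if not self.phases:
            raise ConfigurationError("phases must be non-empty")
        if self.n_afferents < 2:
            raise ConfigurationError("n_afferents must be >= 2 for pairwise correlation")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["frequencies"] = list(self.frequencies)
        d["phases"] = list(self.phases)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        for key, typ in (("afferent", AfferentParams), ("echo", EchoParams), ("analysis", AnalysisKnobs)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        for key in ("frequencies", "phases"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_yaml(path))

    def with_overrides(
        self,
        seed: int | None = None,
        frequencies: tuple[float, ...] | None = None,
        phases: tuple[float, ...] | None = None,
    ) -> "RunConfig":
        cfg = self
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if frequencies is not None:
            cfg = replace(cfg, frequencies=tuple(frequencies))
        if phases is not None:
            cfg = replace(cfg, phases=tuple(phases))
        return cfg
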