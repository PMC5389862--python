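"""File formats: waveform/spike/echo CSV, HDF5 bundles, YAML configs, provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .afferents import SpikeTrain
from .behavior_sim import EchoSeries
from .stimulus import AMWaveform, StimulusSpec


def write_waveform_csv(path: str | Path, am: AMWaveform) -> None:
    pd.DataFrame({"time_s": am.times, "amplitude_mVcm": am.values}).to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spike_trains_csv(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = [(tr.trial_id, t) for tr in trains for t in tr.spike_times]
    pd.DataFrame(rows, columns=["trial", "spike_time_s"]).to_csv(path, index=False)


def read_spike_trains_csv(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(int(trial), np.sort(g["spike_time_s"].to_numpy()), duration)
        for trial, g in df.groupby("trial")
    ]


def write_echo_series_csv(path: str | Path, series: list[EchoSeries]) -> None:
    """Long-format event CSV: one row per stimulus or emitted chirp."""
    rows = []
    for s in series:
        for t in s.stimulus_chirp_times:
            rows.append((s.trial_id, "stimulus", float(t), s.f_beat, s.phase))
        for t in s.emitted_chirp_times:
            rows.append((s.trial_id, "emitted", float(t), s.f_beat, s.phase))
    pd.DataFrame(rows, columns=["trial", "event_type", "time_s", "f_beat", "phase"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# HDF5 bundle helpers


def save_waveform_h5(group: h5py.Group, am: AMWaveform) -> None:
    group.create_dataset("values", data=am.values)
    s = am.spec
    group.attrs.update(
        {
            "f_beat": s.f_beat,
            "delta_f": s.delta_f,
            "delta_t": s.delta_t,
            "contrast": s.contrast,
            "sample_rate": s.sample_rate,
            "total_duration": s.duration,
            "n_beat_cycles_before_chirp": s.n_beat_cycles_before_chirp,
            "chirp_phase": np.nan if s.chirp_phase is None else s.chirp_phase,
        }
    )


def load_waveform_h5(group: h5py.Group) -> AMWaveform:
    a = group.attrs
    phase = None if np.isnan(a["chirp_phase"]) else float(a["chirp_phase"])
    spec = StimulusSpec(
        f_beat=float(a["f_beat"]),
        chirp_phase=phase,
        delta_f=float(a["delta_f"]),
        delta_t=float(a["delta_t"]),
        contrast=float(a["contrast"]),
        sample_rate=float(a["sample_rate"]),
        total_duration=float(a["total_duration"]),
        n_beat_cycles_before_chirp=int(a["n_beat_cycles_before_chirp"]),
    )
    values = group["values"][...]
    times = np.arange(values.size) / spec.sample_rate
    onset = None if phase is None else spec.chirp_onset_time
    return AMWaveform(times, values, spec, chirp_onset_time=onset)


def save_spike_trains_h5(group: h5py.Group, trains: list[SpikeTrain]) -> None:
    """Ragged storage: concatenated times plus per-trial offsets."""
    offsets = np.zeros(len(trains) + 1, dtype=np.int64)
    for i, tr in enumerate(trains):
        offsets[i + 1] = offsets[i] + tr.n_spikes
    times = (
        np.concatenate([tr.spike_times for tr in trains]) if trains else np.empty(0)
    )
    group.create_dataset("times", data=times)
    group.create_dataset("offsets", data=offsets)
    group.attrs["duration"] = trains[0].duration if trains else 0.0


def load_spike_trains_h5(group: h5py.Group) -> list[SpikeTrain]:
    times = group["times"][...]
    offsets = group["offsets"][...]
    duration = float(group.attrs["duration"])
    return [
        SpikeTrain(i, times[offsets[i] : offsets[i + 1]], duration)
        for i in range(offsets.size - 1)
    ]


# ---------------------------------------------------------------------------
# Config serialization and provenance


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path: str | Path, data: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(data: dict[str, Any]) -> str:
    """Stable hash of a config dict (canonical JSON, sorted keys)."""
    blob = json.dumps(data, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(outdir: str | Path, config_dict: dict[str, Any], seed: int) -> None:
    path = Path(outdir) / "provenance.json"
    with open(path, "w") as fh:
        json.dump({"seed": seed, "config_hash": config_hash(config_dict)}, fh, indent=2)
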