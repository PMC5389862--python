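# beatchirp

Tools for studying how the background *beat* frequency shapes the neural
coding and perception of electrocommunication *chirps* in weakly electric
fish, written for computational/sensory neuroscientists working with
electrosensory recordings or models.

When two *Apteronotus leptorhynchus* meet, their electric organ discharges
(EODs, quasi-sinusoidal at individual frequencies near 800 Hz) interfere and
produce a sinusoidal amplitude modulation — the beat — at
`f_beat = |f1 - f2|`. A *small chirp* is a brief (~14 ms) rise of the
emitter's EOD frequency by ~60 Hz; on the receiver's skin it is a fast phase
sweep that perturbs the beat and permanently advances its phase. Because a
chirp can occur at any beat phase and on top of any beat frequency, the same
communication signal produces very different stimulus waveforms, and the
question is which neural representation is *phase invariant* and *detectable*:
single peripheral afferent (P-unit) firing rates, or pairwise correlations
between afferents.

The package provides, as a single tested pipeline over synthetic data (or
user-supplied event files in the same formats):

* beat/chirp AM synthesis with controlled phase, frequency excursion Δf,
  duration Δt, and contrast;
* a P-unit-like generator: `r(t) = clip(r0 + g(f) AM(t), 0, r_max)` with
  high-pass gain `g(f) ∝ f^0.25`, shared EOD-carrier phase locking, and
  inhomogeneous-Poisson spiking — rectifying (firing cessation) at high beat
  frequencies and linear below 10 Hz;
* spike metrics: binary sequences (0.5 ms), PSTHs (0.1 ms bins, 6 ms boxcar),
  beat-phase histograms, and a phase-locking index that counts silent
  histogram bins;
* the time-resolved pairwise spike-count correlation
  `rho = Cov(n_i, n_j) / sqrt(Var(n_i) Var(n_j))` in a window of 12.5 % of
  the beat period (5 bins), sliding by 0.1 % of the period;
* the normalized distance
  `D(x,y) = <(x - <x> - y + <y>)^2> / max[(max x - min x)/2, (max y - min y)/2]`,
  stimulus and neuronal detectability
  `|R_chirp - R_beat| / (R_chirp + R_beat)` (with `R = max - min`),
  invariance scores over the 8-phase stimulus set, and response-duration
  power-law fits `d = a f^b` that set the per-frequency analysis windows;
* an echo-response simulator and analysis (chirp rate and behavioral
  invariance in a 1 s window, moving-block bootstrap errors, block size 31).

## Worked example

A chirp at beat phase 90° on a 2 Hz beat, two simulated afferents, and the
time-resolved correlation between them:

```python
import numpy as np
from beatchirp import (AfferentParams, StimulusSpec, insert_chirp,
                       rate_from_am, sample_spikes, sliding_correlation,
                       window_length)

spec = StimulusSpec(f_beat=2.0, chirp_phase=90.0)     # 60 Hz, 14 ms chirp
am = insert_chirp(spec)
print(f"chirp onset at {spec.chirp_onset_time:.3f} s, "
      f"correlation window T = {window_length(2.0)*1e3:.1f} ms")

pair = [AfferentParams(noise_seed=s, n_trials=200) for s in (1, 2)]
trains = [sample_spikes(rate_from_am(am, p), am.times, p) for p in pair]
ct = sliding_correlation(trains[0], trains[1], spec.f_beat)

t = ct.times - 0.009 - spec.chirp_onset_time          # stimulus-aligned time
beat = np.nanmean(ct.rho[(t > -0.8) & (t < -0.2)])
chirp = np.nanmax(ct.rho[(t > 0) & (t < 0.08)])
print(f"beat-epoch correlation {beat:.3f}, peak after chirp onset {chirp:.3f}")
```

prints

```
chirp onset at 1.125 s, correlation window T = 62.5 ms
beat-epoch correlation 0.044, peak after chirp onset 0.570
```

The chirp is scheduled after two unperturbed beat cycles plus the requested
phase (1.125 s), the analysis window is 12.5 % of the 500 ms beat period, and
the pair is weakly correlated during the beat but transiently synchronized by
the chirp — the low-frequency regime in which correlated activity signals
chirps irrespective of beat phase. At 64 Hz the same computation shows the
opposite: strong beat-locked correlation structure (with mutually silent,
undefined windows) that masks the chirp response.

The full experiment grid (stimulus synthesis → afferent population → scores →
behavior → report) runs from the command line:

```sh
beatchirp all --seed 1 --out runs/demo
beatchirp all --seed 1 --frequencies 2,64 --phases 0,90,180,270 --out runs/small
```

writing the waveforms (HDF5), spike and echo event series, correlation
traces, a tidy `analysis/scores.csv` (beat frequency × phase × source ×
metric), duration fits, behavior summaries with bootstrap errors, and a
`report.json` of trend checks. The stages (`simulate`, `analyze`, `behavior`,
`report`) can be run separately; each consumes the previous stage's files, so
recorded data in the same formats can replace any simulated stage.

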