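# Methods

`beatchirp` simulates and analyzes how the background *beat* frequency shapes
the coding of electrocommunication *chirps* by peripheral electrosensory
afferents (P-units) of the weakly electric fish *Apteronotus leptorhynchus*,
and how it shapes the fish's behavioral *echo response*. The package has two
halves: synthetic-data generators (stimulus, afferent population, behavior)
that define the study conditions, and an analysis chain (spike metrics,
time-resolved pairwise correlation, distance/detectability/invariance scores,
behavioral statistics) that operates identically on simulated or recorded
event series.

## Stimulus model

Two fish with EOD frequencies f1 and f2 produce by interference a sinusoidal
amplitude modulation (AM) at `f_beat = |f1 - f2|`. The AM is synthesized
directly in the envelope domain,

    AM(t) = contrast * sin(Phi(t)),
    Phi(t) = 2*pi * Integral [f_beat + excursion(tau)] dtau,

with phase 0 deg defined at the upward zero crossing, `chirp_phase` the beat
phase at chirp onset (start of the excursion window), and defaults matched to
the standard protocol: contrast 0.34 mV/cm, sampling 10 kHz, beat frequencies
{1, 2, 4, 8, 16, 32, 64, 128} Hz, chirp phases 0–315 deg in 45 deg steps.
A carrier-sum path (two explicit EOD sinusoids plus envelope extraction)
exists only as a test oracle; all analyses operate on the AM.

The small-chirp excursion is a raised Gaussian supported on exactly
`delta_t` = 14 ms: `excursion(t) = delta_f * (exp(-u^2/2) - e^-2)/(1 - e^-2)`
with `u = (t - t_c)/sigma`, `sigma = delta_t/4`, peak `delta_f` = 60 Hz. The
subtraction of the edge value makes the perturbation exactly causal (the AM is
bit-identical to the unperturbed beat before onset) while keeping the peak and
the ±2 sigma duration definition exact; the closed-form area of this profile
(`chirp_profile_area`) fixes the permanent beat phase advance,
`2*pi*Integral(excursion) ≈ 0.45` cycles for the default chirp.

## Afferent model

The firing rate follows the AM through a high-pass gain with hard dynamic-range
limits:

    r(t) = clip(baseline + g(f_inst(t)) * AM(t), 0, saturation),
    g(f) = gain_at_1hz * f**gain_exponent,

where `f_inst(t) = f_beat + excursion(t)`, so the chirp transiently raises the
effective modulation frequency to ~`f_beat + delta_f` and drives strong
responses (saturation or rectification) at every background frequency. Spikes
are an inhomogeneous Poisson process (thinning) whose rate is additionally
multiplied by a unit-mean von Mises comb locked to the EOD carrier
(`eod_frequency`, concentration `eod_locking_kappa`); the comb is identical
for every afferent because the carrier is common, and it is what carries
shared drive at sub-millisecond resolution. An axonal conduction delay
(default 9 ms) is added to every spike so that the conventional 9 ms left
shift of neural traces during analysis re-aligns them with the stimulus.

Default calibration (chosen analytically against the two protocol anchors —
linear responses for beats up to 10 Hz; rectification with a silent fraction
above 25 % of the cycle at 64 Hz):

| parameter | default | rationale |
| --- | --- | --- |
| baseline_rate | 200 Hz | typical P-unit working rate |
| gain_at_1hz | 314 (spk/s)/(mV/cm) | modulation amplitude A(10 Hz) = 190 Hz, just below both clips |
| gain_exponent | 0.25 | shallow high-pass: A(2) = 127 Hz, so slow beats are encoded near-proportionally ("faithfully"), while A(64) = 302 Hz gives an analytic silent fraction of 0.27 |
| saturation_rate | 400 Hz | ~1 spike per two EOD cycles; bounds the chirp transient so it cannot dwarf the beat response |
| eod_frequency / kappa | 823 Hz / 12 | realistic EOD rate, incommensurate with the power-of-two beat set; kappa 12 concentrates firing in ~1/8 of the EOD cycle |
| n_trials | 200 | per (beat frequency, phase) condition |

The rectified-sinusoid silent fraction has the closed form
`1/2 - arcsin(baseline/A)/pi` for modulation amplitude `A > baseline`
(`silent_fraction_analytic`), used both for calibration and as a test oracle.

Why carrier locking matters: pairwise spike-count correlation at 64 Hz is
computed in 0.39 ms bins. An envelope-only Poisson model's expected counts per
bin (~0.1) change far too slowly relative to shot noise, capping rho at
~0.01–0.05, so the beat-locked correlation structure central to the analysis
never appears. With shared carrier locking, both afferents concentrate spikes
on the same EOD cycles and the defined-window rho swings between ~0.02 and
~0.2 over the beat cycle at 64 Hz (and is undefined inside the mutually silent
arc), while windows at low beat frequencies—spanning many EOD cycles—are
unaffected.

## Analysis chain

* **Binary sequences / PSTHs.** Spikes are binned at 0.5 ms (binary sequence)
  or 0.1 ms (PSTH), and PSTHs are smoothed with a 6 ms boxcar (odd kernel,
  reflect padding, integral-conserving). Neural traces are shifted left by
  9 ms.
* **Phase locking.** The phase-locking index is the fraction of
  phase-histogram bins (default 20) whose count falls below
  `0.0005 * mean bin count`; with count data this detects exactly-silent bins,
  so the index responds to rectification and not to smooth rate modulation
  (vector strength is deliberately not used). The threshold factor is
  config-exposed.
* **Sliding correlation.** Window `T = 0.125/f_beat`, 5 bins per window,
  slide step `0.001/f_beat`; the paired sample pools the per-trial, per-bin
  counts of the two afferents, and Pearson rho is computed from exact integer
  sufficient statistics on a micro-bin grid (one window bin = 25 slide steps).
  Zero-variance windows are NaN (undefined), excluded pairwise downstream.
  The pipeline averages rho over all pairs of a 4-afferent population.
* **Distance.** `D(x,y) = <(x - <x> - y + <y>)^2> / max(ptp(x), ptp(y))/2`
  over an analysis window, evaluated as the variance of `x - y` so identical
  traces give exactly zero. D is linear in trace amplitude, so each trace
  *set* entering an invariance ratio is rescaled by its own maximum half
  peak-to-peak range first; this makes the response/stimulus ratio unit-free
  while preserving the two anchor cases (identical responses -> 1, responses
  identical to stimuli -> 0).
* **Detectability.** Stimulus level: D between the chirp AM and the
  phase-matched unperturbed beat over one full beat cycle after onset. Neural
  level: `|R_chirp - R_beat|/(R_chirp + R_beat)` with `R = max - min` of the
  trace, the chirp window from the response-duration power law and the beat
  window one cycle of the beat-only reference run.
* **Response durations.** The no-chirp reference for a chirp trial is the
  beat-periodic prediction (the response delayed by one beat period): the
  chirp permanently advances the beat phase, so the literal unperturbed-beat
  reference never re-converges and would make durations grow with beat
  frequency. The deviation is thresholded at mean + 2 SD of its beat-epoch
  value after boxcar smoothing at the response timescale
  (`max(delta_t, T)`); sub-threshold gaps shorter than the smoothing width do
  not terminate the interval, and durations are capped at
  `delta_t + 1.5` beat periods. Durations per frequency (median over phases)
  are fitted with a log–log least-squares power law `d = a f^b`; the fitted
  windows feed the invariance and detectability scores per source
  (single-unit PSTH vs. correlation time course).
* **Behavior.** Echo emission is a driven point process: baseline rate plus,
  after each stimulus chirp, a Poisson number of echoes (mean
  `echo_gain * drive`) at truncated-normal latencies within the 1 s response
  window. The drive is the per-(frequency, phase) correlation-based
  detectability — the decoding hypothesis made generative, a model choice.
  Chirp rate is the mean emitted count in the 1 s window; behavioral PSTHs
  use 10 ms bins smoothed with a 50 ms boxcar (emissions are sparse events;
  without smoothing, shot noise sets the peak-to-peak normalization scale);
  behavioral invariance reuses the neural invariance score on these PSTHs.
  Errors come from a moving-block bootstrap with block size 31. Emitted-chirp
  characteristics are drawn from one frequency-independent distribution
  (60–150 Hz, 10–20 ms).

## Pipeline scheduling and problem sizes

Each condition plays `max(2, ceil(f_beat/2))` unperturbed beat cycles before
the chirp (at least ~0.5 s of background at high frequencies, so beat-epoch
noise statistics are well estimated) and at least 1.25 cycles after; all
phases at one frequency share one total duration. The default run is 8
frequencies x 8 phases, 4 afferents x 200 trials per condition, and 1000
behavioral trials per condition (the pooled-session equivalent of the tens of
fish and thousands of chirps a behavioral dataset aggregates); it completes in
roughly 6–8 minutes on one CPU. The test suite runs a 6-frequency variant of
the same conditions.

## What the generators do and do not emulate

The generators reproduce the statistical structure the analysis assumes:
stimulus-locked rate modulation with high-pass gain, rectification at high
beat frequencies, carrier-locked firing shared across afferents, trial noise,
and behavioral echo responses whose strength follows a supplied detectability
drive. They do not emulate spike-train regularity beyond Poisson (no renewal
structure or adaptation), afferent heterogeneity, fish-position-dependent
contrast, feedback between behavior and stimulation, or any downstream (ELL,
midbrain) processing. Passing trend tests therefore show that the analysis
chain recovers the designed structure under realistic noise — not that the
generator is a faithful biophysical model of P-units.

## Known limitations

* Single-unit responses over-emphasize the chirp transient relative to real
  P-units even with saturation, so single-unit detectability is somewhat
  high at 1–2 Hz (real curves are uniformly low), though still far below the
  correlation-based values and flat across most frequencies.
* Correlation invariance at 1–4 Hz is depressed relative to real data because
  the chirp-evoked correlation bump amplitude is phase-dependent in a
  count-based Pearson estimator; the plateau/drop structure across frequency
  is reproduced, but micro-ordering among plateau frequencies is noise.
  Consequently the behavioral-vs-correlation invariance curves agree in shape
  and in their 2-vs-64 Hz ordering, while exact rank agreement across all
  frequencies (Spearman exactly 1) is not generally attained: several plateau
  values are tied within estimator noise, and the behavioral invariance is a
  different functional (spread of per-phase detectability scalars) than the
  correlation invariance (trace-shape distances). Chirp rate, by contrast,
  rank-tracks correlation detectability exactly, since the echo generator is
  driven by it.
* Undefined (zero-variance) correlation windows are carried as NaN and
  excluded pairwise; at 64–128 Hz up to ~30 % of beat-epoch windows are
  undefined, which is itself the phase-locking signature.
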