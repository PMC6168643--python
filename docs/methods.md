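# Methods

This note documents the models behind the synthetic generator, the exact
measurement rules, the defaults and why they were chosen, and what the
passing tests do and do not establish about real recordings.

## Synthetic recordings

### Spike trains

Each simulated unit is an inhomogeneous Poisson process whose rate is a
trial-periodic profile `r(t) = r0 · m(t)` relative to stimulus onset, with
`r0` the baseline rate (spikes/s) and `m(t)` built from:

* piecewise-constant **segments** `(t_start, t_end, multiplier)` —
  suppression (multiplier < 1), excitation (> 1), rebound epochs;
* an optional **exponential-recovery** epoch: full silencing at stimulus
  onset with `r(t) = r0 · (1 − exp(−t/τ))` for t ≥ 0.  The analytic time
  at which such a profile re-crosses 50% of baseline is `τ · ln 2`, which
  is what the inhibition-duration rule should recover.

Named presets mirror the canonical response classes of claustrocortical
FFI experiments: `pc_suppressed` (silencing, τ = 352 ms, the value implied
by a 244 ms half-recovery), `in_biphasic` (5× excitation at 7–15 ms, then
suppression to 10% out to 150 ms, matching short-latency interneuron
excitation at ~9.5 ms), `control_flat`, `md_excited` (1.469× for 0–100 ms,
closed-form MI ≈ 0.19), `pv_opto` (τ = 171.7 ms) and `npy_opto`
(τ = 346 ms).

Sampling uses thinning against the profile's maximal rate, followed by
greedy deletion of events closer than the refractory period (default
2 ms, the boundary of the ISI isolation rule).  For `r0 · refractory ≪ 1`
the deletion barely distorts the rate; at 5–20 spikes/s it still shaves a
rate-dependent 1–4% off.  The parameter-recovery experiments in
`ffikit.experiments` therefore generate *exact* Poisson trains
(refractory disabled): the closed-form MI of a configured multiplier
assumes Poisson statistics, and the refractory option exists for
waveform-rendering realism, not rate calibration.

### Extracellular traces

Spikes are rendered as a biphasic difference of Gaussians (negative lobe
σ = w/5 at the event time, positive lobe σ = w/3 scaled 0.4× at lag `w`)
so the planted peak-to-trough width equals `w` up to sample quantization;
the lobes are narrow enough that their interaction shifts the extrema by
far less than one sample at 25 kHz.  Noise is white Gaussian.  Real
recordings have colored noise, but the detection criterion is defined
through the noise SD, so white noise suffices to test the stated rule;
the robust SD estimator behaves conservatively on colored noise.  One
seed sequence per session spawns one child stream per unit (in list
order) followed by one stream for the noise, which makes traces
bit-reproducible from `(config, seed)`.

Default protocol: 200 stimuli per session at 0.2 Hz (one pulse per 5 s)
sampled at 25 kHz.  200 trials keep the Monte-Carlo SE of a per-unit MI
at baseline 5–20 spikes/s near 0.02–0.05, well below the effects being
recovered.

### Intracellular sweeps

PSPs/PSCs are difference-of-exponential kernels
`k(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)` rescaled so the peak equals the
configured amplitude, with an onset delay and a sign (excitatory /
inhibitory).  Trains apply geometric short-term depression: pulse k has
amplitude `A1 · d^(k−1)`, so the adaptation ratio of an n-pulse train is
`d^(n−1)` by construction (0.853⁴ ≈ 0.53 for the default 5-pulse 20 Hz
train).  `kernel_from_kinetics` numerically inverts the map
(τ_rise, τ_decay) → (10–90% rise, half-width) to build kernels with
prescribed kinetics, e.g. the fast-spiking-like (5.6 ms, 46.3 ms) and
neurogliaform-like (22.3 ms, 118.6 ms) centroids.  The number of pulses
per 20 Hz and 50 Hz train defaults to 5 (configurable); paired-recording
bursts default to 50 Hz.

## Measurement rules and defaults

| quantity | rule | default |
|---|---|---|
| band-pass | zero-phase Butterworth, order 3 | 0.3–5 kHz |
| noise SD | median(|x|)/0.6745 | — |
| event threshold | SNR × SD, negative-going | SNR 4 |
| dead time | enforced from the aligned peak | 1 ms |
| isolation | multi iff frac(ISI < 2 ms) > 0.1% (strict) | — |
| cell type | IN iff width < threshold (strict) | 0.4 ms |
| MI windows | 1 s pre, 0.1 s post, trial-averaged rates | — |
| excitation | any 5 ms bin in (0, 30] ms > baseline mean + 4 SD | SD across pre-stimulus 5 ms bins over 1 s |
| latency | 1 ms PSTH peak; jitter/probability from first spike in (2, 20] ms | — |
| inhibition duration | 50% crossings of the smoothed PSTH | 10 ms bins, 3-bin moving average, recovery sustained 2 bins |
| late sort | quartiles by rank over mean normalized rate in (200, 500] ms, stable sort | — |
| onset latency | 10% point of the 10–90% rise; response must exceed 10 pA | 20 ms window |
| IPSP classes | boundaries at the midpoints of the empirical fast/slow centroids | rise 13.95 ms, half-width 82.45 ms |
| connection | across-trial mean post-burst deflection / SEM, z > 3 | 100 ms window |
| firing patterns | FS: peak rate > 100 spikes/s and width < 0.4 ms; NGF-like: last/first ISI < 2 and first spike later than 50% of the just-suprathreshold step | — |
| tests | rank-sum (unpaired, tie-corrected z), paired t; two-sided; Holm adjustment with raw p retained | α = 0.05 |

Notes on the genuinely open choices:

* **Excitation-criterion SD.**  Whether the baseline SD is taken across
  5 ms bins or across trials is not fixed by the rule's usual statement;
  this implementation uses the SD across the pre-stimulus 5 ms bins of
  the same PSTH (1 s window).  Under that reading the null
  false-positive rate on flat units is a fraction of a percent
  (empirically ≤ 3 in 100 units).
* **Inhibition-duration smoothing.**  Raw 10 ms bins of a 10 spikes/s
  unit have a rate SD comparable to the 50% threshold margin, so the rule
  operates on a 3-bin moving average and requires two consecutive bins at
  or above threshold to call recovery.  Durations are measured between
  bin left edges, so they are quantized to 10 ms; for exponential
  recovery the smoothing shifts the crossing by < 0.1 ms (the moving
  average of a convex exponential is nearly its central value).
* **Kinetic crossing times** are linearly interpolated between samples,
  which makes rise times and half-widths sub-sample accurate on clean
  averages; the optional pre-smoothing (`smooth_ms`, used by the pipeline
  on noisy averaged sweeps at 0.5 ms) is off by default because a 0.5 ms
  box filter distorts sub-millisecond rise times by more than the 2%
  accuracy the measurements otherwise achieve.
* **IPSP class boundaries.**  Only the group means of the fast and slow
  kinetic classes are published; the class boundaries here are their
  midpoints, a symmetric and reproducible choice, configurable per study.
  A slow rise with a fast decay has no reading under this scheme and is
  flagged unclassifiable.
* **Connection criterion.**  No explicit statistical rule is published
  for calling a pair connected; this implementation uses the across-trial
  mean deflection in the 100 ms after the burst divided by its standard
  error, z > 3 (one-sided when the deflection sign is known).  With 20
  trials the statistic is Student-t distributed under the null, giving a
  nominal false-positive rate of ~0.4%, matched empirically within
  binomial error.
* **E/I summary** is the mean of per-cell |EPSC|/|IPSC| ratios, which is
  not the ratio of the group means; the per-cell mean is the documented
  summary.
* **MI of bursty excited units** can be negative even when the cell is
  initially excited, because a 100 ms post window averages a brief burst
  with the subsequent suppression.  This is retained as a property of the
  index (the excitation flag captures such units), not corrected.
* **Trial edges.**  Stimuli sit at multiples of the stimulus period, so
  the first trial has no complete pre-window and the last may have no
  complete post-window; metric computations drop stimuli whose analysis
  windows are incomplete.

## Population experiments (`ffikit.experiments`)

* `population_mi`: 100 Poisson units, baselines uniform in 5–20 spikes/s,
  200 stimuli each, rate multiplier on (0, 0.1] s.  The closed forms are
  MI = (m − 1)/(m + 1): −0.81 for m = 0.105, +0.19 for m = 1.469, 0 for
  the unmodulated control.  The mean-of-per-unit-MIs estimator carries a
  small Jensen bias (≈ −0.001 at these counts), well inside the
  Monte-Carlo SE of ~0.003.
* `population_inhibition_duration`: 100 units, 500 stimuli, baseline
  10 spikes/s, full silencing with exponential recovery; the 50% rule on
  the grand-average normalized PSTH recovers `τ ln 2` = 244 ms (τ =
  352 ms) and 119 ms (τ = 171.7 ms) up to the 10 ms bin quantization
  (measured: 240 and 120 ms).
* `train_adaptation_ratio`: one noise-free sweep of five EPSP kernels
  (τ_rise 1.5 ms, τ_decay 10 ms) at 50 ms spacing with retention 0.853;
  per-pulse amplitudes are measured with local-baseline correction (the
  trace value at each pulse onset), which cancels most of the residual
  decay of the preceding response; the measured ratio is 0.527 ≈ 0.853⁴.

These problem sizes were chosen so each experiment's Monte-Carlo error is
well below the effect being recovered while the whole set runs in a few
seconds on one core.

## What the synthetic tests do not show

The generator reproduces the *statistical structure* the measurement
rules are defined on, not the biophysics: no conductance-based neurons or
synapses, no network interactions, white rather than colored noise,
stereotyped waveforms without amplitude drift or overlap between units,
and behavioral states enter only through profile parameters.  Passing
parameter recovery therefore validates the measurement rules and their
implementation — it does not certify performance on recordings with
waveform drift, non-Poisson bursting, or overlapping units.  Two
consequences worth knowing:

* With a 4σ threshold, chance noise events occur at a few tenths per
  second; over minutes of recording they alone can push the close-ISI
  fraction of a genuinely single unit past the very strict 0.1%
  criterion, so long threshold recordings frequently read "multi" — as
  they do in practice.
* Access-resistance-based exclusion of whole-cell recordings is a
  recording-quality step with no computational counterpart here; the
  generator simply does not emulate poor access.
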