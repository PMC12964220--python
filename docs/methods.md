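# Methods

`icloco` implements the analysis chain used to quantify
locomotion-related modulation of single-unit activity in auditory
midbrain recordings from head-fixed mice on a passive treadmill, along
with a synthetic session generator that provides ground truth for every
estimator. This note describes the procedures, their assumptions, the
parameters that matter, and the choices made where the design was
genuinely open.

## Locomotion segmentation

Walking speed is obtained by smoothing the calibrated treadmill trace
with a zero-phase, unit-area 200-ms Hanning window (reflect padding) and
clipping at 0 (optical sensors jitter negative after smoothing).
**Walking periods** are maximal intervals with speed strictly above
2 cm/s; sub-threshold breaks strictly shorter than 200 ms are absorbed.
The session is tiled with half-open 1-s segments `[k, k+1)` from t = 0
(the grid phase is a convention; results are insensitive to it for the
session lengths analyzed) and each segment is labeled *stationary*
(zero overlap with walking periods), *walking* (entirely inside one), or
*partial*; partial segments are excluded from all rate statistics.

**Locomotion onsets** are detected on the raw sensor rather than the
smoothed speed, to avoid the half-window latency the smoothing would
introduce. A sample is "moving" when it deviates from the trailing
0.5-s median by more than 5 % of the session's sensor dynamic range
(max − min). An onset is a stationary-to-moving transition that
(a) follows at least 0.5 s within the band and (b) whose local baseline
sits at the session's resting level (10th percentile of the sensor).
Condition (b) is needed because a steady bout plateau is locally
constant but is not rest; without it, ramp-downs and mid-bout speed
changes register as onsets.

## Per-unit modulation

Spike counts in stationary vs. walking 1-s segments are compared with a
two-sample t test. The unequal-variance (Welch) form is the default
because segment counts are typically unbalanced; the pooled-variance
form is available (`equal_var=True`). A unit is *increased* or
*decreased* when p < 0.01 with the corresponding sign of the mean
difference, *ns* otherwise. Units with fewer than 4 walking segments or
fewer than 2 stationary segments (two being the minimum for a variance)
are *ineligible* and reported as such rather than folded into *ns*, so
population denominators are always explicit. No multiple-testing
correction is applied across units; population proportions should be
read accordingly. The speed–rate correlation is the Pearson r between
per-segment mean speed and per-segment rate over stationary + walking
segments; including the zero-speed stationary anchor makes the sign of
the coupling interpretable for both increased and decreased units
(a walking-only variant can be computed by passing filtered labels).

Unit quality control: inter-spike intervals strictly below 0.7 ms are
refractory violations; a unit passes QC when its violation rate is
strictly below 0.5 %.

## Onset-aligned latency

For each unit, spike counts binned at 1 kHz are scaled to Hz and
smoothed with a unit-area 100-ms Hanning window (the same kernel family
as the speed trace; the rate-trace sampling of 1 kHz makes the 0.5-s
baseline window exactly 500 samples). Traces are cut to ±2 s around
each qualified onset (≥ 10 onsets required, each preceded by ≥ 0.5 s of
stillness) and averaged pointwise. Baseline mean μ and SD σ come from
the averaged profile's samples in [−1.5, −1.0) s; σ is the SD of the
averaged trace, not the mean of per-onset SDs (the alternative is one
line of code but couples the threshold to single-bout variability).

Latency is the first time in (−1.0, +2.0] s at which the profile
exceeds μ + σ (increased) or falls below μ − σ (decreased), subject to
two qualifications that make the crossing the start of a *departure*
rather than a noise excursion:

* **sustained**: the profile must stay beyond the threshold for at
  least one smoothing window (100 ms, `latency_min_hold`);
* **anchored**: the excursion must still be in effect at movement onset
  (or begin after it). Locomotion-related modulation persists through
  the bout, so a pre-onset excursion that dies out before movement
  begins cannot be the modulation's onset.

Both qualifications matter quantitatively: the threshold is defined in
units of the baseline's own noise, so the raw first-crossing rule is
triggered by baseline fluctuations with high probability regardless of
how strong the modulation is. With them, the estimator's remaining
error is the crossing bias of a smoothed step — the profile reaches a
1-σ exceedance partway up the smoothed rise, roughly 25–40 ms before
the true step for high-SNR steps — which is within the half-kernel
tolerance used throughout.

For increased units whose baseline mean is below 0.5 Hz, μ is replaced
by the 0.5 Hz floor before thresholding ("close to 0 Hz" is resolved as
μ < 0.5 Hz); otherwise a near-silent baseline would make the 1-σ
threshold arbitrarily small. Latencies are reported in ms, negative
when modulation precedes the reference onset. `no_crossing` is an
explicit status, not a zero.

**EMG re-referencing.** Latencies measured against treadmill onsets are
re-expressed relative to muscle activation as
`latency_emg = latency_treadmill − median_delay`, with the median
EMG-to-treadmill delay taken from the session's delay distribution.
When per-onset EMG onsets are available, latencies are also recomputed
directly with EMG onsets as the alignment events (both paths are
implemented; the pipeline reports both).

## Bout-wise typing

For units with mean rate ≥ 5 Hz (`boutwise_min_rate`, the package's
resolution of "sufficiently high firing rates"), each bout is typed from
its own ±2 s window: baseline from that bout's [−1.5, −1.0) s; response
= mean rate in [0, +0.5) s. *Increase* if the response exceeds μ + σ;
*decrease* if it falls below μ − σ, or below 0.8 μ when μ − σ < 0 (the
20 %-decrease fallback for noisy low baselines); otherwise *ns*. Bout
latencies use a 2-σ crossing for increases, and for decreases the first
drop below μ − σ or below 0.5 Hz, whichever occurs first — implemented
as a crossing of max(μ − σ, 0.5 Hz), which is equivalent for a
continuous descent. Bouts with truncated windows are skipped with an
explicit status.

## EMG

Raw EMG is bandpassed 20–450 Hz (4th-order Butterworth, zero-phase),
60-Hz notch filtered (Q = 30), downsampled to 2 kHz, rectified,
smoothed with a 100-ms moving average, and normalized to its maximum.
For each treadmill onset, baseline statistics come from the
[−1.0, −0.5) s window before the onset (anchored to the treadmill onset,
the only independently defined reference); the baseline SD is floored at
0.03 — 3 % of the normalized maximum — treated as an SD floor on the
normalized envelope, which keeps the units consistent. The EMG onset is
the first envelope sample within ±0.5 s of the treadmill onset exceeding
mean + 2 × SD. Delays (EMG − treadmill) are negative when muscle
activation precedes treadmill motion; EMG onsets are paired to the
nearest treadmill onset within ±0.5 s, each treadmill onset used once,
unmatched onsets dropped and counted.

## Acoustics

**Footstep SPL.** Audio is bandpassed 1–50 kHz (highpass-only when the
recording's Nyquist is below 50 kHz) and the analytic-signal magnitude
envelope is computed. The event threshold is mean + 4 × SD of the raw
envelope over stationary reference periods; crossings are evaluated on
a 2-ms-smoothed copy of the envelope. The split matters on long
recordings: the threshold characterizes the noise-floor amplitude,
while smoothing the detection statistic removes the sub-millisecond
Rayleigh tail that would otherwise produce isolated one-sample
crossings by the thousands. Supra-threshold runs closer than 50 ms
merge into one event; a merged span must last ≥ 5 ms. The event extent
is the supra-threshold span padded by 5 ms per side, and the event RMS
is computed over that extent of the bandpassed waveform. SPL is
calibrated against a 4-kHz tone of known level:
`SPL = SPL_tone + 20·log10(rms_event / rms_tone)`, which is exactly
scale-invariant. The extent rule introduces a small (< 0.3 dB) bias
relative to a fixed-window RMS because the detected extent and the
nominal event support differ at the amplitude tapers.

**Vibration coupling.** The skull-vibration envelope (60-Hz notch,
rectification, 200-ms moving average, 1 kHz) and the speed trace are
both averaged in 100-ms bins anchored at t = 0 and correlated
(Pearson). Signals that are already envelopes skip the extraction
(`is_envelope=True`). At least 20 common bins are required.

**PSD.** Welch periodograms (segment length 8192 samples, 50 % overlap,
capped at the interval length) are averaged across labeled intervals
with duration weights.

## Synthetic sessions

The generator reproduces the statistical structure the analysis
assumes, with ground truth recorded for every draw. All randomness
descends from one `SeedSequence`, with per-unit substreams spawned
deterministically: a (preset, seed) pair serializes byte-identically.

* **Locomotion**: rest / linear ramp (100–300 ms) / plateau
  (3–15 cm/s) / ramp-down bouts of 3–6 s with ≥ 2.5 s rests, packed with
  Dirichlet-distributed slack. The sensor is a saturating monotone
  transform of speed, `1 − exp(−v / 0.5 cm/s)`, plus noise — steep at
  movement onset, as an optical sensor responding to any motion is —
  which localizes the 5 %-rule onset to a few ms.
* **Spike trains**: inhomogeneous Poisson by thinning; rate =
  base outside modulation epochs, base × gain inside; each epoch runs
  from bout onset + lead to bout end (lead < 0 models predictive
  modulation; the epoch end is tied to the bout end because offset
  dynamics are not separately modeled). A 1-ms absolute refractory
  period is imposed by greedy dead-time deletion — real units have one,
  and the ISI-based QC rule presupposes it — with `refractory=0`
  available for pure-Poisson property tests. Modulation is a rate step,
  not a ramp: the latency definition is a threshold crossing of a
  step-like average.
* **EMG**: Gaussian baseline plus broadband bursts whose amplitude
  ramps linearly over 150 ms from bout onset + delay (locomotor EMG
  builds over ~100–150 ms; the instantaneous SD is linear in the drive,
  the standard recruitment picture, so the rectified envelope ramps
  linearly and the nominal burst onset is the detectable activation
  onset), holds to the bout end, and decays over 100 ms.
* **Vibration**: envelope = coupling × speed + Gaussian noise drawn
  per 100-ms block — the timescale the coupling correlation is measured
  at — so the closed-form calibration
  `sd_noise = a · sd(speed_binned) · sqrt(1/r² − 1)` holds exactly at
  the analysis scale. (White 1-kHz noise of the same SD would average
  down ~10× under 100-ms binning and push r toward 1.)
* **Audio**: a 4-kHz calibration tone of known RMS (5-ms cosine tapers)
  in [0.5, 1.5] s, a guaranteed quiet reference interval [2, 4] s, and
  footstep transients — noise band-limited to 2–10 kHz (the band
  locomotion sounds concentrate in) under a 5/45/30 ms
  rise/flat/decay envelope — whose per-event RMS over the 80-ms support
  is normalized exactly to the target SPL. Background noise is set by
  an amplitude SNR of 10 against the transient plateau. The default
  rate is 50 kHz; pass `rate=250000` for full-bandwidth runs.

**Presets** encode the benchmark population statistics: the
`deaf_population` composition (44 / 22 / 34 % over 146 units, realized
exactly by largest-remainder rounding), modulation-lead distributions
with medians −216 ms (increased) and −88 ms (decreased), an EMG delay
distribution with median −125 ms, 40-dB footsteps against a 60-dB tone,
and a vibration coupling calibrated to r = 0.42. Where only a median is
published, the dispersions are the package's choices (normal leads with
SD 60 / 50 ms; normal delays with SD 40 ms). Per-unit gains are drawn
uniform from [1.5, 4] (increase) and [0.3, 0.8] (decrease) — no
per-neuron gain distribution is published, so these are invented and
configurable — with stronger gains in the latency presets
([5, 8] and [0.02, 0.1] on 2–8 Hz and 25–35 Hz baselines) so that step
amplitudes exceed 5 baseline SDs, the regime in which a 1-σ threshold
crossing dates the step rather than the noise. Base rates are
lognormal (median 6 Hz, σ_log 0.8, clipped to [0.5, 30] Hz), matching
the scale of spontaneous midbrain rates in the deafened condition.

**What the generator does not emulate** — and hence what passing tests
do not establish about real recordings: spike-sorting artifacts and
drift, non-Poisson firing statistics (bursting, adaptation),
rate ramps rather than steps, arousal covariates correlated with but
distinct from locomotion, gait-cycle structure within bouts,
microphone/sensor frequency responses, and session-to-session
heterogeneity. Recovery of the preset statistics shows the estimators
are calibrated under the model's assumptions, not that the assumptions
hold in vivo.

## Study sizes and runtimes

The bundled reproduction studies use the preset sizes throughout: 146
units × 400 s for the composition study, 17 + 7 units × 20 onsets for
the latency studies, 121 onsets for the EMG study, 100 footsteps at
50 kHz, 600 s of vibration, and 1000 null units for the type-I
calibration. These sizes keep every study within seconds on one core
while leaving the binomial/median sampling error well inside each
quantity's tolerance.

## Numerical choices and degenerate inputs

Kernels are forced to odd length so zero-phase smoothing preserves
affine trends exactly; reflect padding conserves spike counts in rate
traces to machine precision. Decimation is by bin-mean with an integer
factor (an error otherwise). Zero-variance t tests (both groups
constant) are defined as p = 1 when the means are equal. Empty spike
trains yield zero rate traces, not errors; ISI statistics on < 2 spikes,
all-zero EMG, missing stationary references, and infeasible bout
packings raise typed exceptions. Threshold comparisons follow the
strict inequalities of the rules they implement (speed > 2 cm/s,
violation rate < 0.5 %, ISI < 0.7 ms). Eligibility failures are
statuses, never silently reclassified.

## Known limitations

The latency estimator retains a systematic early bias of roughly half
the smoothing window at high SNR (the 1-σ crossing happens partway up
the smoothed rise), and its variance does not shrink uniformly with
more onsets because the threshold scales with the baseline noise.
The onset detector's `pre_stationary` is measured from the sensor band
criterion and slightly underestimates true rest time just after a bout
(the trailing median needs ~0.3 s to settle). The EMG onset search
window (±0.5 s) silently misses delays larger than that. Footstep RMS
depends on the extent rule at the ~0.2 dB level. The CLI loads whole
sessions into memory; multi-hour 250-kHz audio should be processed in
chunks outside the bundled pipeline.
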