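# Methods

`olfontogeny` analyzes trial-structured electrophysiology from the
locust olfactory pathway across development: electroantennograms
(EAGs) from the antenna, whole-cell recordings of antennal-lobe
projection neurons (PNs), and local field potentials (LFPs) from the
mushroom-body calyx, all recorded around a 1 s odor pulse. This note
documents the procedures, the conventions adopted where the field has
no single operational definition, and what the synthetic generators do
and do not emulate.

## Data model

Trials carry their own stimulus (odor label, onset, duration) and
animal metadata (age group: hatchling / 10 d / 20 d / adult; intact
antennal-segment count where tracked). Units are fixed at seconds,
millivolts and hertz at the API boundary; files may declare ms or µV
and are converted on load. Time zero is the trace start and the
stimulus onset is carried explicitly, because every analysis needs a
pre-stimulus baseline window. The on-disk format is a JSON manifest
plus one plain-text file per trial (spike times or samples, one per
line), chosen for diffability over compactness.

## EAG tuning

The peak response to an odor is the maximum absolute deviation from
the pre-onset baseline (mean of all pre-onset samples) within 2 s of
onset. Absolute deviation is used because EAG deflections are
conventionally negative-going; no literature definition of "peak
amplitude" pins the sign convention. Each animal's panel is normalized
by its own hexanol peak, so hexanol is 1 by construction and is
excluded from between-group tests. Age groups are compared odor-by-odor
with two-sample t-tests — Welch by default, since group sizes differ
and variances are not assumed equal; the pooled-variance Student
variant is an option — at a Bonferroni-corrected alpha whose divisor
defaults to the number of odors actually tested (override available).
A dummy-coded OLS, amplitude ~ age + stimulus (both categorical),
summarizes the age effect in a single coefficient.

## PN response complexity

The complexity statistic counts transitions between excitatory and
inhibitory firing epochs in a 4 s window from odor onset:

1. **Responsiveness gate.** Rates in 400 ms histogram bins; the
   baseline is the pre-stimulus bin rate averaged across the pair's
   trials. A trial is responsive in a bin when its rate differs from
   baseline by more than one SD of the pre-stimulus bin rates. The SD
   is pooled over pre-stimulus bins of all trials by default (the
   highest-powered reading; a per-trial SD option exists). A PN–odor
   pair enters only if some bin is responsive in at least half its
   trials; every trial of an included pair then contributes one count.
2. **Rate estimate.** Instantaneous rate as the inverse inter-spike
   interval on a 1 ms grid; zero before the first and after the last
   spike, where 1/ISI is undefined.
3. **Smoothing.** Truncated unit-sum Gaussian kernel, SD 33.33 ms,
   support 200 ms (6 SD). Edges are reflect-padded so a constant
   series passes unchanged and no spurious edge valleys arise.
4. **Extrema.** A lookahead/delta detector: the scan tracks the
   running candidate maximum (minimum); a peak (valley) is confirmed
   when the series falls below the candidate by more than `delta`
   (rises above by `delta`) with no higher (lower) sample inside the
   200 ms lookahead horizon. Extrema alternate strictly and the very
   first confirmation — seeded at the series boundary — is discarded,
   following the widely used published form of this algorithm.
   `delta` defaults to one SD of the smoothed pre-onset rate, tying
   the prominence floor to the responsiveness criterion; both
   parameters are exposed.
5. **Counting.** Each valley strictly between the first and last
   in-window peak counts twice (excitatory→inhibitory and back). A
   first in-window peak later than 200 ms after onset adds a
   spontaneous→excitatory transition; a last in-window peak before the
   window end adds an excitatory→baseline transition. The boundary
   increments attach to the first and last peak only, so interior
   epochs are not double-counted beyond their valleys.

Per-age distributions of counts are compared with a two-sample
Kolmogorov–Smirnov test (exact p for n ≤ 10 per sample, asymptotic
otherwise). Mean firing rates (evoked: [onset, onset + 4 s];
spontaneous: 2 s pre-onset; the source figures do not define these
windows, so they are package conventions) are compared with a two-way
ANOVA on age × odor, Type II sums of squares by default (robust to
the mildly unbalanced design; Type III uses sum-to-zero contrasts).

### Recovery limits of the transition count

The smoothed 1/ISI estimate of a Poisson train with rate λ has
sampling SD ≈ sqrt(λ / (2·√π·σ)) ≈ 2.9·√λ Hz at σ = 33.3 ms. The
detector confirms a spurious peak–valley pair whenever the smoothed
series swings by more than `delta` around its running extremum, so
per-trial exact recovery of a profile's ground-truth count requires
rate excursions of roughly 8 sampling SDs, i.e. λ ≳ 300 Hz for
epoch-length segments — attainable only in the low-sampling-noise
regime. The tests therefore check *modal* recovery at adult-like
burst rates (120 Hz epochs: ~80% of trials exact, mode equals truth)
and ≥90% per-trial exact recovery for well-separated high-contrast
epochs (500 Hz, `delta` ≈ 3.7 SD). Noiseless profiles fed directly
into the smoothing–detection–counting chain reproduce their
ground-truth counts exactly, by construction of the ground-truth
oracle.

## LFP oscillations

Signals are band-passed 3–50 Hz with a 4th-order Butterworth filter
applied forward–backward; zero-phase filtering preserves the onset
latencies measured later. Spectrograms use a 0.5 s Hann window with
50% overlap (2 Hz frequency resolution, 0.25 s hop, no zero-padding).
Trials 3–10 are averaged — oscillations usually develop only after
two odor presentations — and the peak frequency is the power argmax
over [3, 50] Hz within 1 s after odor onset (an absolute-time window
override exists for records whose onset convention differs).

A peak is flagged low-confidence when its power is below 3× the
median power *of the same frequency row across all time columns*,
i.e. when the putative burst is no stronger than the ongoing
background at that frequency. A guard against the in-window median
across all frequencies (the more obvious choice) fails under 1/f-like
backgrounds, whose lowest bins dominate any median; the row-relative
test is what actually separates odor-locked bursts from noise.

Oscillation properties come from the analytic-signal (Hilbert)
envelope of the band-passed trial average: amplitude is the post-onset
envelope maximum; duration is the longest contiguous span above the
pre-onset envelope mean + 2 SD (floored at 5% of the post-onset
maximum so a noise-free baseline does not reduce the threshold to
zero); latency is the first crossing after onset, reported missing if
the envelope never crosses. These are explicit conventions — the
source material reports the properties without operational
definitions.

**Antennal trimming.** For each recording side, trials are grouped by
(antenna, stage), each group's trials 3–10 are spectrogram-averaged,
and the per-stage peak frequency is regressed on the number of cuts by
OLS with intercept (one point per antenna-stage). A side whose
frequencies never change (common for the untrimmed control after 2 Hz
binning) is reported as slope 0, p 1 rather than as a degenerate fit.

## Synthetic data

The generators emulate the statistical structure each analysis
assumes, with ground truth stored for recovery tests; identical
(config, seed) pairs give identical datasets.

* **Spike trains** are inhomogeneous Poisson processes (thinning)
  following piecewise-constant rate profiles of excitatory and
  inhibitory epochs over a baseline, with 2 s of pre-onset baseline
  and 6 trials per pair. The per-age default profiles (adult baseline
  5 Hz with 40/25 Hz epochs, hatchling 2 Hz with 15/9 Hz epochs,
  intermediate ages interpolated) are plausible locust PN values
  chosen to give the qualitative adult > hatchling rate ordering; no
  measured rates are claimed. A profile's ground-truth transition
  count is always computed by running the noiseless profile through
  the analysis chain, never hand-entered.
* **LFP trials** are AR(1) background noise (φ = 0.98 at 1 kHz, a
  smooth 1/f-like spectrum without band-edge artifacts) plus an
  odor-locked burst: a sinusoid with raised-cosine on/off ramps,
  random phase per trial, 10 trials per condition. Burst frequency
  follows the drive map f(n) = max(f_floor, f_ref − slope·(n_ref − n))
  with f_ref = 20 Hz at 25 segments and slope 0.52 Hz/segment;
  amplitude scales with segment count. Age defaults (amplitude 0.05 →
  0.20 mV, duration 0.8 → 1.5 s, latency 0.15 → 0.35 s from hatchling
  to adult) reproduce direction only; the hatchling frequency is the
  drive map evaluated at 12 segments, not a measured value. The trim
  generator adds a slow per-stage frequency drift (SD 0.75 Hz, shared
  between sides) emulating physiological non-stationarity; without it
  the 2 Hz bins quantize every control-side estimate to the same
  value.
* **EAG trials** are difference-of-exponentials deflections (rise
  50 ms, decay 500 ms), negative-going, with per-odor mean peaks
  (hexanol 2.0 mV largest) drawn at 20% between-animal CV plus 10 µV
  trace noise; age groups share means by default, emulating the
  absence of peripheral tuning differences, and a configurable shift
  injects a known age effect for recovery tests.

What the generators do **not** emulate: spike-train refractoriness and
burst ISI structure (Poisson only), non-sinusoidal oscillation
waveforms and cycle-frequency drift within a burst, electrode drift
and movement artifacts, odor-specific LFP differences, and any
correlation between modalities recorded from the same animal. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated statistical model, not robustness to every property
of real recordings — in particular, trial-averaged envelope measures
degrade on real (non-phase-locked) data, which is why the spectrogram
path averages power, not traces.

## Problem sizes in tests

The default suite uses 10-trial LFP conditions, a 3-antenna trim
cohort over stages 25→15 segments, 100-trial Poisson recovery runs,
and 500 replicate EAG datasets (9 vs 8 animals) for the type-I-error
calibration; these sizes give Monte-Carlo error comfortably inside
every asserted tolerance while keeping the suite fast.

## Known limitations

* Exact small-sample KS p-values delegate to scipy's exact method;
  ties in integer count data make the asymptotic p conservative.
* The per-trial transition count is sensitive to the detector `delta`
  at realistic firing rates (see the recovery-limit analysis above);
  comparisons between groups should use one fixed configuration.
* The low-confidence flag for peak frequency is a heuristic; it is
  reported alongside, never used to drop data silently.
* The regression treats antenna-stages as independent observations,
  matching the source analysis; a mixed model with per-antenna
  intercepts is out of scope.
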