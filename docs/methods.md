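# Methods

## Problem and signal model

A chest-worn optical sensor injects light into the skin and measures the
diffusely reflected intensity at a nearby photodetector. Chest-wall motion
stretches the skin under the patch and modulates the collected intensity, so
the photodetector series carries a quasi-periodic breathing waveform: a
fundamental at RR/60 Hz (RR = respiratory rate in breaths per minute, bpm)
plus weaker higher-order harmonics, on top of slow baseline drift (posture,
perfusion), broadband noise, and occasional large motion or cough
transients. The clinically relevant range is roughly 6–41 bpm.

`rrband` estimates RR per 60-s window from such a series, and evaluates the
estimates against per-minute reference breath counts with Bland–Altman
style agreement statistics.

## Conditioning chain

Each window is conditioned in a fixed order before counting:

1. **Moving average** over `ma_points` samples (default 15 at 50 Hz ≈
   0.3 s), centred, to remove high-frequency noise. Edge samples are
   handled by shrinking the window symmetrically to what fits, so the filter
   is length-preserving and invents no data at the window boundaries; the
   first and last samples pass through unchanged. An even length behaves as
   the next-lower odd length (the window stays symmetric).
2. **Baseline removal**: subtraction of a centred moving mean over
   `baseline_window_s` = 12 s. The slowest in-range rate (6 bpm) has a
   10-s period, so 12 s is the shortest window that removes drift without
   eating the slowest breathing; the 0.3-Hz fundamental passes with < 10%
   attenuation. A constant input maps to exactly zeros.
3. **Motion detection** with the Teager–Kaiser energy operator
   ψ[x](n) = x(n)² − x(n−1)·x(n+1). For a pure sinusoid ψ is the constant
   A² sin²(Ω); motion transients raise it by orders of magnitude (ψ scales
   with amplitude squared *and* frequency). Because the raw ψ of a
   harmonic-rich breathing waveform oscillates within each breath cycle
   (peak/median ratios above 10 even for clean signals at 8–18 bpm), ψ is
   first smoothed into a 5-s envelope; a sample is flagged when the envelope
   exceeds `k_thresh` = 10 × its window median, and flags are dilated by
   0.5 s on each side. With the 5-s envelope the clean-signal worst-case
   peak/median ratio over 6–41 bpm is ≈ 2.3, leaving a comfortable margin
   below the threshold while a 1-s transient at 10× breathing amplitude
   exceeds it by orders of magnitude.
4. **Motion correction**: flagged runs are replaced by linear interpolation
   between the nearest clean neighbours (edge runs held at the nearest
   clean value). Windows with more than 25% of samples corrected are
   flagged `low_quality` and excluded from evaluation, mirroring how
   interrupted reference minutes are excluded.
5. **Saturation**: a recording whose samples sit on an ADC rail for ≥ 0.5 s
   is treated as corrupted in full and excluded (per-window exclusion is a
   config switch away). Rails are optional; without them the check reports
   "not applicable" rather than false.
6. **Buffering** into consecutive non-overlapping 60-s windows aligned to
   the recording start; a trailing remainder < 60 s is dropped. The
   alignment matches a protocol in which device and manual counting start
   concurrently and are compared at exact 60-s marks.

All second-denominated parameters are converted to samples by rounding to
the nearest integer. The sampling rate defaults to 50 Hz — comfortably
above the third breathing harmonic at the fastest in-range rate
(3 × 41/60 ≈ 2 Hz) — and is configurable; file readers infer it from
timestamps when present.

## Breath counting

The counter is a hysteresis mean-crossing detector. Within a conditioned
window, a breath onset is a negative-to-positive crossing of the window
mean that first dips below mean − h and then rises above mean + h, where
h = `hysteresis_frac` (default 0.2) × half the 5th–95th percentile
amplitude span. Onsets closer than `min_breath_period_s` are merged. With
k ≥ 2 onsets spanning T seconds the fractional rate is 60(k−1)/T; fewer
than two onsets is a `no_breaths` failure. The percentile-based hysteresis
makes the count exactly invariant to amplitude scaling and offsets.

## Adaptive sub-banding

A single parameter set cannot serve the whole range: long smoothing and a
long minimum breath period are right for slow breathing but cap or distort
fast breathing; short settings admit fast rates but let noise split slow
breaths into spurious onsets. The two-pass scheme:

1. Pass 1 conditions and counts with the default parameters (15-point
   smoothing, minimum period 60/55 s so all rates up to 50 bpm are
   reachable).
2. The pass-1 rate selects a band from the table below (half-open
   [low, high) intervals; a rate on a shared bound belongs to the upper
   band; rates ≥ 27 clamp into the top band).
3. Pass 2 re-runs the *full* conditioning from the raw window with the
   band's parameters and recounts. Exactly two passes; no iteration even
   if the corrected rate lands in a different band. A pass-2 counting
   failure falls back to the pass-1 value flagged `low_quality`, preserving
   the minute's pairing with its reference count.

Default band table:

| band (bpm) | ma_points | min breath period (s) |
|-----------|-----------|----------------------|
| [0, 20)   | 15        | 60/25 = 2.40         |
| [20, 27)  | 12        | 60/32 = 1.875        |
| [27, 50)  | 9         | 60/55 ≈ 1.09         |

The low/high smoothing lengths (15 and 9 points) are the established
values for low and high bands; the middle 12 is their interpolation. The
per-band minimum breath period 60/(high + 5) lets each band admit rates
slightly beyond its upper edge, so a modest pass-1 underestimate cannot
lock the true rate out. In "normal" (non-adaptive) mode only pass 1 runs.

Under ward-grade noise the dominant failure of the normal mode is
overcounting at slow rates — noise-induced crossings pass the short default
minimum period — and the low band's 2.4-s merge window is what removes it;
this is where the sub-banding accuracy gain comes from.

## Synthetic data

The simulator is phenomenological, not biomechanical. The breathing
component is Σ_h a_h sin(h·φ(t)) with a piecewise-linear phase advancing 2π
per breath; breath periods are jittered multiplicatively (coefficient of
variation `rate_jitter_cv`, normal, clipped at ±3 CV). Harmonic amplitudes
default to (1, 0.4, 0.15), qualitatively matching the visible second and
third harmonics of real chest-optical spectra. Drift is a slow sinusoid,
noise is white Gaussian, artifacts are Hann-windowed 8-Hz bursts, and
saturation is hard clipping at the rails. Ground truth (onsets, per-window
fractional rates, integer per-minute onset counts standing in for manual
counts) comes from the same generated breath periods, and everything is
reproducible from the scenario seed.

The **standard noisy scenario** used for noisy-cohort evaluations is
noise σ = 1.0 relative to the fundamental (SNR ≈ 0 dB), drift amplitude
0.5 at a 45-s period, and 5% period jitter — chosen to stress the
estimator the way general-ward recordings do and to produce
device-reference deviations on the few-bpm scale reported for bedside
respiratory wearables. Presets mirror the recognised clinical failure
modes: `cough_scenario` (1-s transients at 10× amplitude) and
`fast_shallow_scenario` (30–41 bpm, fundamental × 0.3, noise × 2).

What the simulator does **not** emulate: optical tissue physics, sensor
electronics, real motion spectra (artifacts are a single burst shape),
non-stationary breathing patterns (apnoea, Cheyne–Stokes), or correlated
noise. Passing tests therefore demonstrate correctness of the algorithms
under the stated waveform model, not clinical performance.

## Agreement evaluation

Per-minute deviations (device − reference) are pooled across subjects at
the minute level. Bias is the mean deviation; the SD uses the n−1
denominator. The 95% interval is by default the empirical (2.5th, 97.5th)
percentile pair of the deviations; parametric Bland–Altman limits of
agreement (bias ± 1.96·SD) are available by flag. The empirical default
was chosen because published agreement tables for this class of device
report asymmetric intervals that are inconsistent with bias ± 1.96·SD; only
a percentile reading reproduces that asymmetry.

Four cases cross reference handling with processing mode: cases 1–2 keep
only subjects whose reference minutes are all non-interrupted, cases 3–4
keep subjects with ≥ 1 clean minute and drop the interrupted minutes; odd
cases use normal processing, even cases sub-banding. Subgroup statistics
split at 55 years of age and add box-plot summaries (median, quartiles,
1.5×IQR whiskers).

## Numerical choices and degenerate inputs

- The moving average anchors its cumulative sum at the first sample so a
  constant input is an exact fixed point (no rounding residue).
- Breath-onset times accumulate float error of order 1e−13 over a 5-min
  recording; per-minute bins are therefore evaluated with a 1-ns tolerance
  so boundary onsets never land in the wrong minute.
- An all-flagged window is uncorrectable and raises; a window with zero
  amplitude span yields `no_breaths`; an empty band table, a gap between
  bands, or a table not covering [0, 50) bpm is rejected at load time.
- Everything is deterministic: identical inputs, parameters and seeds give
  byte-identical outputs (estimates, stats, logs).

## Evaluation problem sizes

The validation protocol uses 120-s recordings for the noise-free sweep over
all integer rates 6–41 bpm, a 20-subject × 5-min cohort (100 windows) for
the noisy mode comparison, and a 100-subject stratified cohort
(4 saturated, 14 fully interrupted, 18 partially interrupted) for the case
bookkeeping and per-case statistics.

## Known limitations

- The breath counter assumes a single dominant oscillation per window; it
  reports one rate and no within-window variability.
- Reference counts derived from simulated onsets are integer truncations of
  a fractional process; device estimates are fractional, so a small
  positive bias against integer references is expected and visible in the
  synthetic cohort results.
- The sub-banding benefit is demonstrated on the standard noisy scenario;
  on clean signals the two modes agree by construction, and on artifact
  regimes outside the simulator's model the benefit is unquantified.
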