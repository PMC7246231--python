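# rrband

Respiratory-rate (RR) estimation from chest-worn optical diffuse-reflectance
signals, with adaptive **sub-banding**, a synthetic-signal simulator, and
Bland–Altman agreement evaluation against per-minute reference counts.

## What it does

A chest patch that measures diffusely reflected light picks up chest-wall
motion: the photodetector intensity carries a quasi-periodic breathing
waveform (fundamental at RR/60 Hz plus harmonics) over drift, noise, and
motion artifacts. `rrband`:

- conditions the raw signal (centred moving average, moving-mean baseline
  removal, Teager–Kaiser energy motion detection with interpolation-based
  correction, rail-saturation gating) and buffers it into 60-s windows;
- counts breaths per window with a hysteresis mean-crossing detector and
  refines a fractional rate from the onset timestamps:
  RR = 60(k−1)/T bpm for k onsets spanning T seconds;
- applies **adaptive sub-banding**: a first-pass rate selects a band from
  {[0, 20), [20, 27), [27, 50)} bpm, and the window is re-conditioned and
  re-counted once with that band's own parameters (15/12/9 moving-average
  points; per-band minimum breath interval 60/(high+5) s);
- simulates realistic cohorts with exact ground truth (breath onsets,
  per-minute integer reference counts, interrupt/saturation labels);
- evaluates agreement: per-minute deviations d = device − reference, bias
  = mean(d), SD (n−1), and a 95% interval (empirical 2.5/97.5 percentiles by
  default, or parametric limits of agreement bias ± 1.96·SD), stratified
  over four cases (exclude/include interrupted minutes × normal/sub-banded
  processing) and by age group.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and limitations.

## Worked example

```bash
# simulate a noisy 3-subject cohort (5-min recordings, 4 reference counts each)
rrband simulate --cohort 3 --noise 0.5 --jitter 0.05 --seed 4 --out demo/

# estimate one subject's per-minute rates with sub-banding
rrband estimate --signal demo/signal_000.csv --mode subbanded --out demo/est0.csv

# run the four-case agreement evaluation
rrband evaluate --manifest demo/manifest.csv \
    --reference demo/reference_counts.csv --out demo/eval
```

The `evaluate` step prints the per-case agreement table, e.g.:

```
case  manual_count_type processing_type  n  bias_bpm  std_bpm  ci95_low_bpm  ci95_high_bpm      interval_method
   1 exclude_interrupts          normal 12 -0.130812 0.364900     -0.812996       0.446596 empirical_percentile
   2 exclude_interrupts       subbanded 12 -0.135170 0.367287     -0.819765       0.446596 empirical_percentile
   3 include_interrupts          normal 12 -0.130812 0.364900     -0.812996       0.446596 empirical_percentile
   4 include_interrupts       subbanded 12 -0.135170 0.367287     -0.819765       0.446596 empirical_percentile
```

Each row is one evaluation case: `n` paired minutes, the mean deviation
(bias) of device minus reference in bpm, its standard deviation, and the
95% interval of deviations. This small cohort has no interrupted minutes
(cases 1/3 and 2/4 coincide) and at moderate noise both processing modes
land within ±0.4 bpm of the reference; under heavier ward-grade noise the
sub-banded rows show the smaller bias and spread (the library-level
evaluation in `scripts/acceptance.py` demonstrates this on a 100-subject
cohort).
`rrband report --deviations demo/eval/deviations.csv --out demo/report`
adds Bland–Altman plots and the age-group subgroup table.

Python API equivalent:

```python
import rrband as rb

raw, truth = rb.simulate_signal(rb.SimScenario(rr_bpm=18, duration_s=300, seed=1))
estimates = rb.estimate_series(raw, rb.default_band_table(), mode="subbanded")
print([float(round(e.rr_bpm, 2)) for e in estimates])   # [18.0, 18.0, 18.0, 18.0, 18.0]
```

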