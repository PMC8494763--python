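# facegaze

Analysis of **face gaze** — gaze directed at an interaction partner's face —
from frame-coded mobile eye-tracking recordings of dyadic conversations,
such as physician–patient consultations.

Wearable eye-trackers combined with face area-of-interest (AOI) detection
yield, for every video frame (40 ms by default), a binary code: the
wearer's gaze point fell inside the partner's face AOI (1) or not (0).
`facegaze` turns such streams into the three standard gaze measures and the
analyses built on them:

* **duration per minute** — seconds of face gaze per analysed minute,
* **frequency per minute** — number of gaze *instances* (onsets of
  uninterrupted face gaze) per analysed minute,
* **mean dwell time** — seconds of gaze per instance.

For a stream with ON-seconds $T_{on}$, instance count $k$ and analysed
minutes $M$, the measures are $d = T_{on}/M$, $f = k/M$ and
$w = T_{on}/k$, so $d = f \cdot w$ holds exactly on every segment with at
least one instance. Frames flagged invalid (physical-examination gaps,
tracker dropouts) leave both numerator and denominator of every rate and
interrupt gaze instances.

On top of the measures the package provides:

* **decile time-courses** — each consultation's valid frames are split into
  10 contiguous bins and a linear mixed model
  $y_{cd} = \beta_0 + \beta\,(d - 5.5) + b_c + \varepsilon_{cd}$, with a
  random intercept $b_c$ per consultation, estimates the change per decile;
* **measure inter-correlations** — pairwise Pearson correlations among
  duration, frequency and dwell, each tested at the Bonferroni level
  $\alpha = 0.05/3 \approx 0.017$, plus uncorrected correlations of each
  measure with patient satisfaction (0–100 VAS) and consultation length;
* **thin-slice prediction** — does the first 30 / 60 / 120 s predict the
  rest? `remainder ~ intercept + slice + total_minutes` by OLS, optionally
  refit with a per-physician random intercept and compared by a
  boundary-corrected likelihood-ratio test;
* a **synthetic-cohort generator**: an alternating ON/OFF renewal process
  (lognormal gaze episodes, gamma gaps) with independent person-level
  duration and frequency traits, a within-consultation decline, and a
  satisfaction outcome linked to gaze frequency. Raw consultation video
  can rarely be shared, so every analysis here is exercised end-to-end on
  seeded simulated cohorts with realistic structure (16 physicians, 2–14
  patients each, consultations of 3–45 min).

## Worked example

```python
import facegaze as fg

config = fg.SyntheticConfig()                       # calibrated defaults
streams, cohort = fg.sample_cohort(config, seed=42)

measures = fg.measures_table(streams)
print(measures[["duration_per_min", "frequency_per_min", "mean_dwell_s"]]
      .median().round(2))

deciles = fg.decile_table(streams)
print(fg.DecileTrendModel(deciles, measure_name="duration").fit().summary())

for c in fg.pairwise_correlations(measures):
    print(c)

splits = [sp for sp in (fg.split_slice(s, 60.0) for s in streams) if sp]
print(fg.fit_slice_model(splits, "dwell", with_physician_effect=True).summary())
```

prints

```
duration_per_min     25.77
frequency_per_min    25.60
mean_dwell_s          0.98
dtype: float64
Decile trend for duration (mixed fit)
  consultations: 113   observations: 1130
  slope per decile (beta): -1.2924  [95% CI -1.3546, -1.2303]   p = 0
  level at mid-consultation: 28.104
  random intercept sd: 11.2725   residual sd: 3.0610
duration-frequency: r = -0.138, p = 0.146 (n = 113, alpha = 0.017)
duration-dwell: r = 0.739, p = 9.14e-21 (n = 113, alpha = 0.017) *
frequency-dwell: r = -0.627, p = 1.08e-13 (n = 113, alpha = 0.017) *
Thin-slice model: dwell, slice 60 s (n = 113)
  intercept:          +0.104 (NS)
  slice measure:      +0.748 ***
  total minutes:      +0.003 (NS)
  R^2:                0.907 (91%)
  physician random intercept sd: 0.048; LRT = 0.000, p = 0.5 -> random effect does not improve fit
```

Reading this: the cohort's median physician gazes at the patient's face
about 26 s per minute, in about 26 instances per minute of roughly 1 s
each. Gaze duration declines by about 1.3 s/min per decile of
consultation time. Duration and frequency are uncorrelated — they capture
different aspects of gaze — while dwell time, being their quotient,
correlates positively with duration and negatively with frequency.
The first minute of gaze strongly predicts the remainder (here
R² = 0.91 for dwell), and a per-physician random intercept adds nothing:
gaze style belongs to the dyad, not to the physician.

## Command line

```bash
facegaze simulate --seed 42 --out-dir data/          # stream CSVs + cohort.csv
facegaze measures --input data/ --out measures.csv
facegaze deciles  --input data/ --out deciles.csv
facegaze trend    --deciles deciles.csv --out trend.csv
facegaze correlate --measures measures.csv --cohort data/cohort.csv --out corr.csv
facegaze thinslice --input data/ --slices 30,60,120 --out table2.csv
facegaze report   --seed 42 --out-dir results/       # the whole chain at once
```

Stream files are tidy CSVs with header `frame_idx,aoi_hit,valid`
(`valid` optional); the cohort table has
`consultation_id,physician_id,satisfaction`.

## Documentation

See `docs/methods.md` for the underlying model, the generator's
calibration and its limitations, and the numerical conventions
(segment-boundary policy, gap masking, degenerate fits).
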