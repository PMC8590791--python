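# wristpa

Wrist-accelerometry processing and repeated-measures analysis of daily
physical activity, with first-class synthetic ground truth.

The pipeline converts raw triaxial acceleration (gravitational units,
fixed sampling rate) into gravity-corrected activity epochs and daily
summaries:

1. **ENMO epochs** — per-sample Euclidean norm minus one, negatives
   truncated to zero, averaged over 5-s epochs (`wristpa.raw`).
2. **Non-wear detection** — 60-min sliding windows flagged when at least
   two axes show near-zero SD or range (`wristpa.raw.detect_nonwear`),
   plus a simplified offset/gain calibration against local gravity.
3. **Intensity classification** — cut-offs 0.03 / 0.1 / 0.4 g for light /
   moderate / vigorous activity, sedentary below 0.03 g; ≥10-min MVPA
   bouts; per-day summaries; valid days at ≥10 h wear; subjects included
   when each measurement week has ≥4 valid weekdays and ≥1 valid weekend
   day (`wristpa.classify`).
4. **Analyses**
   - relative-intensity audit of absolute MET-anchored cut-offs against
     each subject's %V̇O₂peak scale, bands <46 / 46–<64 / 64–100 / >100%
     (`wristpa.relative`);
   - most-active 10-h window of each day and the distribution of its
     midpoints (`wristpa.window`);
   - random-intercept linear mixed models for day-of-week,
     weekend-by-week, reactivity and season effects (adjusted for age,
     sex, V̇O₂peak and daily wear time, optional per-factor-level variance
     weights), weekday/weekend sleep regression, and a Wilcoxon rank-sum
     wear-time comparison (`wristpa.stats`);
   - the 30-s rolling-mean peak-V̇O₂ rule for exercise tests
     (`wristpa.raw.peak_vo2`).

`wristpa.synthetic` generates raw signals with planted activity /
non-wear / sleep segments whose per-sample ENMO is exact by construction,
and daily-summary tables with known injected effects and covariates drawn
from published cohort moments — every stage is testable against ground
truth.

## Command line

```sh
# synthetic raw data + truth + daily table (reduced scale via config)
wristpa --config config.txt simulate --out out/sim

# raw CSVs -> epoch CSVs + daily summaries + validity report
wristpa --config config.txt process --raw-dir out/sim --out out/processed

# analyses
wristpa --config config.txt audit-cutoffs --subjects out/sim/subjects.csv --out out/audit.json
wristpa --config config.txt windows --epoch-dir out/processed --out out/windows
wristpa --config config.txt stats --daily out/sim/daily.csv --out out/stats.json

# everything, deterministically
wristpa --config config.txt --seed 7 run-all --out out/run
```

Configuration is a `key = value` text file (see `wristpa.config` for all
keys); defaults follow the published protocol values (50 Hz, 5-s epochs,
0.03/0.1/0.4 g, 60-min non-wear windows, 600-min valid day, 10-h window,
46/64/100% bands). Raw CSV format: header
`timestamp_iso8601,x_g,y_g,z_g`, one row per sample, local civil time.

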