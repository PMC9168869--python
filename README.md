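# circahrv

Circadian heart-rate-variability (HRV) trend analysis for wearable
inter-beat-interval (IBI) recordings.

Long-term wearable photoplethysmography yields days to weeks of
beat-to-beat intervals per subject. Single-time-point HRV measurements
are dominated by circadian fluctuation and day-to-day noise; `circahrv`
instead estimates each subject's *circadian HRV trend* — a smooth curve
of normalized HRV over a standardized wake-anchored day — and asks in
which part of the day (or between which parts) two groups of subjects
differ. The approach was developed for studying cardiac autonomic
dysfunction in multiple sclerosis, where disease activity and
progression leave signatures in the circadian adaptation of autonomic
tone, but the pipeline is agnostic to the clinical question.

## Pipeline

For each subject:

1. **Artifact screen** — beat *i* is an artifact iff
   `|IBI_i − med_i| > max(c · QD_i / 0.6745, 50 ms)`, where `med_i` and
   the quartile deviation `QD_i` are taken over the 41-beat neighborhood
   excluding beat *i* (a robust z-score with default `c = 3.32`).
   Flagged runs are removed and replaced by linearly interpolated beats
   that conserve the gap's elapsed time.
2. **Segmentation** — non-overlapping 5-min segments; segments with an
   interpolated run longer than 4 beats, excessive movement (above the
   subject's 90th wake percentile by default), or too few beats are
   discarded.
3. **Metrics** — per segment: SDNN, RMSSD, pNN20/pNN50, Poincaré
   SD1 = RMSSD/√2 and SD2 = √(2·SDNN² − RMSSD²/2) (so
   SD1² + SD2² = 2·SDNN² exactly), and Welch LF/HF band powers on the
   4 Hz-resampled tachogram. Group analysis uses SDNN, SD1, SD2.
4. **Normative percentage scores** — each metric is divided by an age-,
   sex- and hour-of-day-specific reference value (metric% = 100 ×
   metric / reference), removing demographic and time-of-day structure.
5. **Standardized day** — labeled wake and sleep intervals map clock
   time onto [0, 1): wake occupies [0, 0.5), sleep [0.5, 1), each phase
   linearly rescaled. All days are superimposed.
6. **Trend** — a degree-10 least-squares polynomial (Chebyshev basis,
   margin points replicated across the periodic boundary) per metric;
   the trend is summarized by the medians of ten 0.1-wide windows
   (five wake + five sleep "20% bins").
7. **Discrimination** — subjects are scored by the trend median over
   each of the 30 contiguous within-phase windows (or by the difference
   Δ between two windows, 435 pairs), and selectors are ranked by
   |AUC − 0.5|. The best selectors carry DeLong 95% CIs,
   Mann-Whitney-U p-values, Benjamini-Hochberg adjustment over the
   search family, standardized mean differences with CIs, and a
   confounder screen (age, gender, medication).

A synthetic-cohort generator (`circahrv.synthetic`) produces
wearable-like IBI/activity/sleep streams from a block-stationary
Gaussian AR(1) model with closed-form metric oracles
(SDNN = σ, RMSSD = σ√(2(1−ρ)), SD1 = σ√(1−ρ), SD2 = σ√(1+ρ)),
planted beat-split/merge artifacts, and calibrated between-group
effects in chosen circadian windows — so every pipeline stage has a
ground truth to be tested against.

## Worked example

```python
import numpy as np
from circahrv import synthetic, pipeline
from circahrv.discriminate import search_single
from circahrv.types import WindowSpec

# a 10 + 10 subject, 7-day cohort with a true group difference
# (SMD = 1.2 on SDNN%) in the 40%-80% sleep window
cfg = synthetic.CohortConfig(
    n_per_group=10, days=7, seed=42,
    group_effects=[synthetic.GroupEffect(WindowSpec("night", 2, 3), "sdnn_pct", 1.2)],
)
subjects, metadata, ledger = synthetic.generate_cohort(cfg)
table = synthetic.generate_normative_table(seed=0)

cohort = pipeline.analyze_cohort(subjects, metadata, table)
labels = cohort.metadata["group"] == "patient"
best = search_single(cohort.trends, labels, grouping="pwMS")[0]
print(best.selector.label(), best.metric,
      round(best.auc, 3), np.round(best.auc_ci, 3), round(best.p_mwu, 4))
```

prints

```
40%-100% night sdnn_pct 0.91 [0.682 0.979] 0.0022
```

i.e. the search recovered a window overlapping the injected region: the
median of the fitted SDNN% trend over the 40%-100% sleep window
separates the groups with AUC 0.91 (DeLong 95% CI 0.68-0.98),
Mann-Whitney p = 0.0022. With no injected effect the best AUC hovers
near 0.5.

The same analysis runs from CSV files via the command line:

```bash
circahrv simulate --seed 42 --n-per-group 10 --days 7 \
    --effect night,2,3:sdnn_pct:1.2 --out data/
circahrv run --config pipeline.yaml
```

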