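# Methods

This note documents the models, estimators and numerical choices behind
`circahrv`, and what the synthetic test surface does and does not
establish about real wearable data.

## Signal model and the synthetic cohort

Real wearable IBI streams are unavailable without a data-sharing
agreement, so the package ships a generator whose outputs exercise every
pipeline stage against a known ground truth.

**Beat model.** Within each 5-minute block, inter-beat intervals are a
stationary Gaussian AR(1) process with block-wise parameters evaluated
at the block's standardized-day position: mean IBI `m(pos)`, marginal
SD `σ(pos)` and lag-1 autocorrelation `ρ(pos)`. The standardized state
is carried across block boundaries, so the lag-1 structure holds through
parameter changes. AR(1) was chosen because it gives closed forms for
every metric the pipeline computes —

    SDNN = σ,  RMSSD = σ√(2(1−ρ)),  SD1 = σ√(1−ρ),  SD2 = σ√(1+ρ)

— turning the simulator into an oracle rather than merely a fixture.

**Default circadian profiles** (chosen once as typical adult resting
physiology): mean IBI 960 + 120·cos(2π(pos − 0.74)) ms (≈71 bpm
mid-afternoon, ≈56 bpm mid-sleep), σ(pos) = 45 + 15·cos(2π(pos − 0.72))
ms (5-min SDNN ≈30 ms by day, ≈60 ms at night), ρ(pos) = 0.45 +
0.18·cos(2π(pos − 0.72)). Schedules default to 16 h wake / 8 h sleep,
wake onset 07:00 ± 30 min across subjects, with 20-min Gaussian
day-to-day jitter.

**Artifacts** are the two failure modes of beat detection: *splits*
(one interval becomes two short ones, u and 1−u fractions with
u ~ U(0.35, 0.65)) and *merges* (two intervals collapse into their
sum), inserted as a Poisson process at 2 events/h by default; the
affected output-beat indices are recorded as ground truth. The default
rate is a placeholder for a well-attached medical-grade sensor, not an
estimate of any particular device.

**Activity** is near-zero noise during sleep and moderate noise plus
Poisson bursts (2/waking hour, 2–10 min, gamma amplitudes) during wake,
at 1 Hz.

**Between-subject structure.** Each subject's σ profile is scaled by
`a · g(sex, age)` with `a ~ LogNormal(0, τ)`, τ = 0.25 (between-subject
coefficient of variation ≈25%, typical for normalized HRV), and `g` the
same demographic factor the synthetic normative table uses — so
percentage scores cancel demographics by construction, as they should.

**Effect injection.** A group effect (window, metric, target SMD)
multiplies the case group's target metric inside the window by
`f(pos) = 1 + (κ−1)·sin²(π(pos−lo)/(hi−lo))` (a raised-cosine taper;
SDNN% effects act on σ, SD1%/SD2% effects on ρ so the other metrics are
left alone). κ is calibrated in two steps: (i) the closed-form relation
between the target SMD and the case/comparison ratio *r* of the window
median under log-normal subject scales,
`SMD = (r−1) / (cv·√((1+r²)/2))` with `cv = √(exp(τ²)−1)`; (ii) a root
find of κ such that the *actual* trend-fit operator (noiseless profile
curve → degree-10 fit with margin replication → window median) produces
ratio *r*. Step (ii) matters: the polynomial smooths the in-window bump,
and a calibration ignoring that attenuation would undershoot the
realized effect. Residual bias (segment noise, normative-cell
perturbations, schedule jitter) is small and verified empirically in the
test suite.

**What the simulator does not emulate.** Day-to-day physiological
variability beyond schedule jitter (the profiles are identical every
day), nonstationarity within blocks, respiration-driven spectral peaks,
posture/exercise transients, PPG waveform artifacts beyond
splits/merges, and missing wear time. Two consequences to keep in mind:
day-subset stability correlations on simulated subjects are higher
(≈0.999 at 7 of 14 days) than real cohorts show (≈0.95–0.96), because
only sampling noise distinguishes days; and spectral/nonlinear
cross-domain correlations (SD1%~HF%) are attenuated relative to real
data because the per-segment Welch estimate is noisy while the AR(1)
parameters drift only slowly. Passing tests certify the estimators and
the search machinery, not device-specific robustness.

## Preprocessing

**Artifact criterion.** Beat *i* is flagged iff
`|IBI_i − med_i| > max(coef · QD_i / 0.6745, floor)` with the median and
quartile deviation computed over the `window_beats = 41`-wide
neighborhood *excluding* beat *i* (windows clamped at the ends).
Dividing QD by 0.6745 converts it to a robust SD, so `coef = 3.32` is a
z-threshold (~0.1% two-sided on clean Gaussian variability); the
`floor = 50 ms` guard prevents flagging in ultra-low-variability sleep.
All three are configurable. The inner scan is a numba kernel
maintaining a sorted sliding buffer (exact, validated against brute
force; a pure-numpy fallback exists).

**Correction.** Each maximal flagged run becomes one gap; the gap is
filled with `k = round(gap / local mean IBI)` (≥1) beats ramping
linearly between the flanking intervals and rescaled to conserve the
gap's elapsed time exactly. Runs touching the series boundary lack a
flank and are dropped. Timestamps are rebuilt cumulatively.

**Validity.** Non-overlapping 300-s windows from recording start
(trailing remainder dropped). A segment is invalid if its longest
interpolated run exceeds 4 beats, else if mean movement magnitude
exceeds the activity threshold, else if it has fewer than `min_beats =
100` beats; the first matching rule is recorded. The default activity
threshold is subject-specific — the 90th percentile of wake-segment
mean activity — since absolute movement units are device-dependent; an
absolute override exists. `min_beats = 100` guards metric stability at
extreme bradycardia.

## HRV metrics

SDNN uses the n−1 sample SD; pNNx uses strict `> x` ms. SD1/SD2 come
from the RMSSD/SDNN identities rather than ellipse fitting — this is
the standard Poincaré estimator and yields the exact conservation law
SD1² + SD2² = 2·SDNN², which the tests assert to 1e−9 relative on every
segment. LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) integrate a Welch
periodogram (120-s Hann windows, 50% overlap) of the mean-removed
tachogram resampled at 4 Hz by cubic spline. Group analysis defaults to
SDNN%, SD1% and SD2%: pNN/RMSSD are largely redundant with SD1 and the
spectral metrics are the least reliable on wearable PPG, but all eight
metrics remain computable and exportable.

Normative lookup floors the age into its containing band and uses the
integer hour of the segment midpoint in local clock time; cells are not
interpolated because published reference tables are banded.

## Standardized day and trend

Wake and sleep phases occupy fixed halves of the standardized day
([0, 0.5) and [0.5, 1)) regardless of actual durations — this is what
makes ten equal "20% bins", five per phase, comparable across subjects
with different schedules. Segments outside labeled intervals are
dropped with a log message.

The trend is an ordinary least-squares polynomial of degree 10 per
metric over all superimposed days. Numerics: degree 10 on [0, 1] is
badly conditioned in the monomial basis, so the fit uses a Chebyshev
basis over the margin-extended domain; the fitted function is
basis-independent and noiseless polynomials of degree ≤ 10 are
recovered to machine precision. Points within `margin_fraction = 0.15`
of each boundary are replicated across the periodic boundary
(end-of-sleep copied before wake onset and vice versa) to suppress
edge oscillation; for periodic data the interior changes by <1%.
Replication is a periodic-continuation prior — exactness for
non-periodic polynomials holds only with `margin_fraction = 0`. With
too few points the degree drops to n−2 (logged); below 4 points the fit
refuses.

Window medians are medians of the *fitted curve* on a 1,000-point
uniform grid per 0.1-wide bin (not medians of raw points) — the curve
is the quantity the method stabilizes, and bin medians of the curve are
insensitive to uneven segment coverage.

**Stability analysis** refits the trend on every combination of k
recorded days (all combinations up to `max_combinations = 5000`, else a
seeded sample without replacement) and Pearson-correlates the
ten-median vector with the full-data vector.

## Discrimination

Selectors are the 30 contiguous within-phase windows and the 435
unordered window pairs (value = median over A − median over B).
Windows never span the wake/sleep boundary. Ranking is by |AUC − 0.5|
(orientation-free) rounded to 12 decimals — AUC is a rational with
denominator m·n, and the rounding makes exact ties break on the
deterministic (metric, phase, start, end) order instead of float
summation dust — while reported AUCs stay oriented to the positive
class.

**DeLong interval.** The AUC variance uses DeLong's structural
components (n−1 sample variances of the per-case and per-comparison
placement values). The 95% CI is formed on the log-odds scale and
mapped back: the plain Wald interval's small-sample coverage sits at
the edge of the nominal band (measured 93.2% at n = 20+20), while the
logit form measures 95.9% and keeps bounds inside (0, 1). Degenerate
AUCs of exactly 0 or 1 fall back to the clipped Wald form.

**Statistics battery.** Mann-Whitney-U is two-sided, exact for
tie-free samples with both n ≤ 8, otherwise normal approximation with
tie and continuity correction (all-identical inputs return p = 1,
SMD = 0). SMD is Cohen's d with pooled n−1 SD, case minus comparison
(negative values mean the case group is lower), CI from the standard
asymptotic variance. Correlations report Pearson and Spearman with
Fisher-z CIs; binary covariates enter as 0/1 (point-biserial).
Benjamini-Hochberg adjustment is applied over one search report (all
selectors × metrics of that search) — the family is configurable since
reasonable alternatives exist (per metric, per analysis). The
confounder screen tests age by correlation and gender/medication by the
group comparison at α = 0.05. Cohort description uses chi-square with
Yates continuity correction for 2×2 tables and uncorrected Pearson for
larger ones (zero-margin rows dropped), Mann-Whitney-U for continuous
fields.

Best-window p-values are reported for the selected window without
selection adjustment — the selection is part of the method being
replicated — and the honest null behavior of the whole search is
established separately by the exchangeability tests (no injected
effect → best |AUC − 0.5| within the permutation null).

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; per-subject
generators derive from a root `SeedSequence`, so identical configs give
bit-identical streams, tables and result files. The test suite's
problem sizes are chosen to exercise each claim at the scale that makes
it sharp: closed-form recovery on ≥50k-beat streams (sampling error
≪2%), effect recovery on fifty independent 30+30-subject, 14-day
cohorts (binomial resolution ~4% on a 90% criterion), DeLong coverage
on 1,000 simulated cohorts, and brute-force equivalence on 12-subject
fixtures where exhaustive enumeration is exact. Cohort streams are
generated one subject at a time (`synthetic.iter_cohort`) so peak
memory stays near a single subject's arrays (~30 MB per 14-day
recording).

## Known limitations

- Sleep/wake labels are taken as given (the optional activity-based
  auto-labeler is a convenience heuristic, not part of the method).
- Naps and split sleep are not modeled; each day contributes one wake
  and one sleep interval.
- The normative table is synthetic: smooth cosine hour-shapes with mild
  demographic modulation. Results on real data require a real
  population reference in the same CSV schema.
- The degree-10 polynomial can ring when a subject has large unlabeled
  gaps; the margin replication mitigates boundary ringing only.
- Selection-adjusted inference (permutation-corrected best-window
  p-values) is not enabled by default, matching the replicated
  analysis.
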