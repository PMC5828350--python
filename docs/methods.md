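# Methods

This note documents the models and procedures implemented in `wearcohort`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Intraday processing and completeness

Timestamps are treated as local wall clock; day boundaries are local
midnight and no timezone arithmetic is performed (the intended setting is a
single-site study). Step intervals tile the day half-open on a 15-minute
grid, so an HR reading exactly on an interval boundary belongs to the
interval starting there. A clock hour is *valid* when it contains at least
one HR reading with confidence ≠ −1 (`min_points_per_hour` is configurable;
the default of one reading reflects that confidence codes, not reading
density, indicate wear). A day is *complete* with ≥ 20 valid hours and at
least one step interval. Overlapping sleep sessions are retained with a
warning and per-day durations sum raw session lengths without unioning;
sessions are attributed to the calendar day they start on, a deterministic
rule that keeps duration sums unambiguous for sessions crossing midnight.

Readings outside (30, 220) bpm are physiologically implausible for this
population and are dropped with a warning before any averaging.

## Metric definitions

Resting HR pools qualifying readings (valid confidence, enclosing interval
≤ 100 steps) across all complete days rather than averaging per-day means;
the pooled form weights days by their data yield and is the natural reading
of "average over time points". The ×96 daily-step estimator averages over
*distinct* enclosing intervals containing at least one valid reading, so an
interval sampled by three HR points is not triple-weighted; a per-point
variant is available behind a flag. Sleep-onset averaging maps starts
before 4 AM onto a +24 h scale before the mean (so 23:30 and 00:30 average
to midnight, not midday) and the same continuous scale is used when the
2-SD filter and cluster comparisons consume sleep hours. The 2-SD filter is
an all-of rule: a subject outlying on any supplied metric is excluded from
that metric family's analyses; missing values never exclude, and a
zero-variance metric retains everyone.

## Activity profiles and clustering

Smoothing is a centred 5-bin moving average whose edge windows shrink to
the available bins; a circular (midnight-wrapping) variant exists behind a
flag but is off by default because first/last bins of a day are usually
sleep. Per-day profiles are smoothed, averaged bin-wise across complete
days over observed values, zero-filled where no day observed the bin, and
smoothed again.

Clustering is Lloyd's algorithm under d = 1 − Pearson: assignment minimises
d with ties to the lowest cluster index; the centroid update is the
arithmetic mean of member profiles (the standard update; under correlation
distance the mean is not the exact Fréchet minimiser, so the iteration
stops as soon as the objective would not improve, keeping the recorded
inertia trace non-increasing). Zero-variance profiles sit at distance 1
from everything, which keeps the operation total; they join the
lowest-index tied cluster and are logged. Each of 100 restarts (default
seed 20180227) seeds k centroids from distinct profiles; an emptied
cluster is re-seeded with the farthest point. With k = 3, labels are
canonicalised post hoc by centroid peak hour (earliest = AM, latest = PM),
so outputs are stable across seeds and restarts.

Because the assignment step depends only on profile shape, cluster
*memberships* are invariant to positive per-subject rescaling; the mean
update makes cluster *numbering* depend on row order, which is why the
invariance is checked up to relabeling.

## Association models

All fits use maximum likelihood via statsmodels GLM/OLS with female as the
gender reference level. Confidence intervals are Wald-type on the link
scale, exponentiated to OR scale where applicable; in an exponentiated
result the `estimate` column stays on the log-odds scale and `or_`,
`ci_low`, `ci_high` are on the OR scale. Non-convergence, separation and
rank deficiency (e.g. an interaction in a single-gender cohort) yield a
flagged result with no estimates rather than a misleading fit. Missing
model variables drop subjects per model (complete case) with n reported;
an optional common-subset mode restricts every risk model to subjects with
all metric types observed, making metrics directly comparable.

Activity categories use the linear-interpolation quantile (the common
default; configurable) with boundary values in the lower category, and the
upper-quartile indicator for the high-LVM model is strictly above the 75th
percentile. The 2-SD inclusion rule for cardiac models is applied to the
analysis-ready outcome (indexed where applicable), per parameter. LVM,
LVEDV and RVEDV are regressed on the BSA-indexed scale; AoF raw with
weight and height as covariates (a flag switches to raw outcomes).
Chi-squared tests in the cohort summary use no continuity correction by
default (configurable). The GPPAQ physical-activity index is the standard
4 × 4 occupation × exercise-hours cross-tabulation with cycling hours
deliberately ignored, which makes the index comparable to wearable-derived
activity. No multiplicity correction is applied across the nine risk
markers; FDR control applies only within the lipidomics family, defined as
all species surviving the odd-chain and missingness filters.

For sphingolipid names, chain parity is evaluated on every chain the name
exposes: per-chain counts for `Cer(d18:1/17:0)`-style names, the total
carbon count for `SM(36:1)`-style names — the only reading the name grammar
supports. The species–glucose models treat the lipid as outcome and fasting
glucose as predictor with the same covariates as the steps model.

## The synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Cohort scale and composition: 233 subjects, 58.8 % female,
ages 21–69 (truncated normal, mean 46, SD 12), ethnicity ~91 % Chinese,
tracking 2–6 calendar days (mode 4) with a partial first day and usually a
partial last day, so most subjects yield 1–4 complete days. Three activity
archetypes (AM/MidDay/PM, weights 62:108:63) define 96-bin intensity
curves peaking at 08:30, 13:00 and 18:30 with matching sleep onset/wake
times (23:18/06:39, 23:40/07:43, 00:07/08:10); per-subject timing jitter
(SD 0.75 h) and a lognormal daily-total scale (mean 10,850 steps/day,
CV 0.36) provide within-archetype heterogeneity. Bin-level step counts are
negative binomial (dispersion 3) for realistic burstiness.

Heart rate is resting level + circadian cosine (amplitude 7 bpm, peak
14:30) + 0.045 bpm per concurrent step + N(0, 3) observation noise;
the resting level is N(69.7, 6.5) shifted by −0.252 bpm per 1,000 expected
daily steps. Readings are invalid (confidence −1) at rate 0.03 and step
intervals are dropped at rate 0.02. In-clinic ECG HR sits 5 bpm below the
wearable resting level (SD 7.4) and the blood-pressure-monitor HR 9 bpm
above ECG (SD 10.7), reproducing realistic Bland–Altman geometry.

Risk markers are drawn flag-first from logistic links (intercepts implied
by the tail mass of each marker's continuous distribution at its
threshold; OR ≈ 1.04–1.07 per bpm resting HR; male × steps interaction ORs
of 0.710/0.760/0.800 for BMI/WC/TG), then the continuous value is drawn
from the matching truncated normal, so dichotomisation exactly reproduces
the links while marginal means track a realistic cohort. Cardiac
parameters follow linear links on the indexed scale (slopes 0.353, 0.386,
0.617, 0.466 per 1,000 steps for LVM/LVEDV/RVEDV/AoF) and are stored raw
(indexed value × BSA) so the pipeline must re-index them. The lipid panel
(first 112 subjects, two batches with different affine raw scales) carries
12 truly coupled species with slopes −0.043…−0.073 SD per 1,000 steps, 28
null species, 4 odd-chain species and 2 high-missingness species that the
filters must remove; because raw abundances are affine in the latent
signal per batch, the within-batch z-score recovers it exactly.

Randomness splits hierarchically (cohort seed → one stream per subject,
consumed in a fixed order), so adding a subject never perturbs the others
and identical config + seed gives byte-identical output.

**What the generator does not emulate:** device firmware quirks beyond
invalid-confidence codes and dropped intervals, naps and fragmented sleep
(one session per night, so simulated sleep durations run ~1 h longer than
typical cohort self-report), diet and other confounders of the
activity–marker links, within-subject day-to-day activity-level trends,
and measurement drift between clinic devices. Passing recovery tests
therefore demonstrates correctness of the estimators and models under the
stated data-generating process, not robustness to every artefact of real
tracker data.

## Problem sizes and numerical choices

Simulation-based tests run at the scales the analyses target: cohorts of
150–500 subjects for clustering and estimator-agreement checks, 2,000
subjects × 200 replicates for logistic-interaction coverage, 500 × 50 for
cardiac-slope coverage, and 112 × 200 for lipid-slope coverage and FDR
behaviour — sizes chosen to give stable Monte-Carlo estimates while the
whole suite stays runnable on a laptop. At the lipidomics scale (8 true
slopes of −0.06 SD per 1,000 steps among 48 species, n = 112, residual SD
0.95 calibrated to published standard errors at this design), the
simulated mean true-discovery fraction at q < 0.1 is ≈ 0.48 with mean
false-discovery proportion ≈ 0.09 — the tests assert these oracle-computed
bands. BH adjustment is the step-up q_(i) = min_{j≥i} m·p_(j)/j capped at
1, cross-checked against statsmodels. k-means determinism is guaranteed by
a single seeded generator across restarts; Lloyd iterations stop on a
1e-10 relative objective change or 300 iterations.
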