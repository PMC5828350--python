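# wearcohort

Analysis pipeline for short consumer-wearable studies in cardiometabolic
cohorts: from raw intraday tracker exports to resting heart rate, daily-step
and sleep metrics, diurnal activity-profile clustering, and association
models against clinical risk markers, cardiac MRI parameters and serum
sphingolipids. A fully parameterised synthetic-cohort generator with
recorded ground truth makes every stage testable end to end without any
real participant data.

It is written for biostatisticians and epidemiologists who have per-subject
wearable exports (step counts in 15-minute intervals, heart rate at 5-minute
cadence with a device confidence code, sleep sessions) plus clinical tables,
and want the derived metrics and models in reproducible, scriptable form.

## The method

**Data completeness.** HR confidence codes indicate device wear; readings
with confidence −1 are invalid. A calendar day is *complete* when ≥ 20 clock
hours contain a valid reading and intraday step data exist for the day. All
metrics are restricted to complete days.

**Wearable metrics.** Resting heart rate is the mean of valid readings whose
enclosing 15-minute interval recorded ≤ 100 steps; day and night HR apply
the same rule inside the 2–4 PM and 2–4 AM windows. Daily steps are
estimated two ways — the mean of within-day interval sums, and 96 × the mean
HR-matched interval count — which agree closely when little data are
missing (Spearman r_s > 0.95 on simulated cohorts). Sleep duration sums
session lengths per day; sleep onset averages session start hours in the
7 PM–4 AM window on a +24 h scale (reported mod 24). Subjects outside
cohort mean ± 2 SD on any sleep metric are excluded from sleep analyses.

**Activity clustering.** Each subject's complete days collapse into a 96-bin
time-of-day step profile, smoothed twice with a centred 5-bin moving
average. Profiles are clustered by k-means (k = 3) under the correlation
distance d(p, q) = 1 − r(p, q), so clusters capture *when* people move, not
how much; clusters are named AM / MidDay / PM by centroid peak timing.

**Association models.** Clinical markers are dichotomised at standard
thresholds (BMI > 27.5 kg/m², WC > 100/90 cm by gender, SBP > 140 mmHg,
DBP > 90 mmHg, TC > 6.2, HDL < 1, LDL > 4.1, TG > 2.3, FBG > 6 mmol/l; all
strict). Step-based metrics enter logistic models as
`marker ~ age + gender + steps + gender:steps` with the gender × steps
interaction reported as an OR per 1,000 steps (female reference); HR-based
metrics as `marker ~ age + gender + hr`, OR per bpm. Cardiac MRI parameters
(LVM, LVEDV, RVEDV indexed to Dubois BSA = 0.007184·W^0.425·H^0.725; AoF
raw) are regressed on steps per 1,000 or on four activity categories cut at
the 10th/50th/90th percentiles, adjusting for age, gender and SBP (plus
weight/height for AoF) after a 2-SD inclusion rule; a logistic model
estimates the odds of abnormally high indexed LVM (> 70 g/m² male,
> 50 g/m² female) for subjects in the upper quartile of daily steps.
Sphingolipid species (odd-chain and > 20 %-missing species removed,
abundances z-scored within batch) are regressed on steps per 1,000 with
age, gender and BMI as covariates, under Benjamini–Hochberg FDR control
(q < 0.1) across species.

## Worked example

```bash
python examples/03_activity_clustering.py
```

```
clustered 86 subjects, k=3, inertia 4.24
cluster sizes: {'MidDay': 38, 'PM': 28, 'AM': 20}
adjusted Rand index vs generating archetypes: 0.966
  AM: centroid peak at 07:45
  MidDay: centroid peak at 13:15
  PM: centroid peak at 18:15
```

Ninety simulated subjects were generated from three diurnal archetypes,
their activity profiles built from the intraday streams, and clustered.
The adjusted Rand index of 0.966 says the recovered clusters almost
perfectly match the archetypes that generated the data; the centroid peaks
show the clusters are morning-, midday- and evening-dominated days.

```bash
python examples/05_cardiac_remodeling.py
```

```
slope per 1,000 daily steps (indexed outcome; AoF raw):
  lvm    beta +0.684 (+0.449, +0.920) p=0.000 n=203  [generating beta +0.353]
  lvedv  beta +0.404 (+0.121, +0.687) p=0.005 n=198  [generating beta +0.386]
  ...
abnormally high indexed LVM, upper-quartile steps: OR 3.04 (1.10-8.42) p=0.032 n=185
```

Each slope is the change in the BSA-indexed cardiac parameter per 1,000
additional daily steps, with the generator's true coefficient shown for
comparison. The other examples (`examples/01`–`06`) cover generation,
metric derivation, risk-marker models and lipidomics in the same style.

There is also a thin CLI over the same functions:

```bash
wearcohort simulate --seed 1 --n-subjects 50 --outdir cohort/
wearcohort all --indir cohort/ --outdir results/
```

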