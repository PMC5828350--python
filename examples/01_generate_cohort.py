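"""Generate a small synthetic wearable-study cohort and look at its truth table.

The generator emulates a short consumer-wearable study: a few days of
15-minute step counts and 5-minute heart rate per subject, sleep sessions,
plus linked clinical, cardiac MRI and serum sphingolipid tables. Every
latent parameter is recorded so downstream estimates can be checked
against ground truth.
"""

import wearcohort as wc

cfg = wc.SynthConfig(n_subjects=20, seed=7)
cohort = wc.generate_cohort(cfg)

sid, sub = next(iter(cohort.subjects.items()))
print(f"cohort of {cfg.n_subjects} subjects; first subject {sid}:")
print(f"  {len(sub.steps)} step intervals, {len(sub.hr)} HR points, {len(sub.sleep)} sleep sessions")
print()
print("truth table (first rows):")
cols = ["subject_id", "archetype", "daily_total_true", "rhr_true", "n_days"]
print(cohort.truth[cols].head().round(1).to_string(index=False))
print()
print("archetype = diurnal activity pattern (AM/MidDay/PM peak);")
print("daily_total_true = expected steps per full day; rhr_true = true resting HR (bpm).")
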