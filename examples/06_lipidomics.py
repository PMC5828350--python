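"""Test serum sphingolipid species for association with daily steps.

Species are filtered (odd-chain and >20%-missing removed), z-scored
within acquisition batch, and regressed on daily steps (per 1,000)
adjusting for age, gender and BMI, with Benjamini-Hochberg FDR across
species. A parallel model uses fasting glucose as the predictor.
"""

import wearcohort as wc
from wearcohort import pipeline

cohort = wc.generate_cohort(wc.SynthConfig(n_subjects=233, seed=2))
mtable, _, _ = pipeline.wearable_stage(cohort.subjects)
table = pipeline.lipid_stage(mtable, cohort.clinical, cohort.lipids)

tested = table[table["p_steps"].notna()]
sig = tested[tested["q_steps"] < 0.1]
print(f"{len(tested)} species tested after filtering "
      f"({len(cohort.lipids.columns) - 2} measured); {len(sig)} at q < 0.1:")
for _, r in sig.iterrows():
    print(f"  {r['species']:<22} beta {r['beta_steps']:+.3f} per 1,000 steps, "
          f"p={r['p_steps']:.4f}, q={r['q_steps']:.3f}")
print()
print("Negative slopes: circulating ceramides/sphingomyelins are lower in more")
print("active subjects (the generator couples the true species at -0.04 to -0.07 SD per 1,000 steps).")
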