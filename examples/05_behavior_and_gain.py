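"""Lying behavior contrast and average daily gain.

Hourly accelerometer epoch counts are pooled into pre- (48 h) and
post-dehorning (168 h) lying proportions per arm, contrasted with
two-proportion z tests and a difference-in-differences; body weights
yield per-calf average daily gain compared across arms by ANOVA.
"""

import numpy as np

from calfpkpd import (
    StudyConfig,
    adg,
    compare_groups_anova,
    generate_cohort,
    minutes_per_day_difference,
    prepost_treatment_contrast,
)

cfg = StudyConfig(seed=1)
cohort = generate_cohort(cfg, include=("behavior", "weights"))

contrast = prepost_treatment_contrast(cohort.behavior, cohort.assignments)
print("lying proportions (pooled epochs):")
print(contrast.table.round(4).to_string())
ctrl = contrast.table.loc["control"]
print(f"\ncontrol calves stand "
      f"{round(minutes_per_day_difference(ctrl['p_pre'], ctrl['p_post']))} "
      f"extra minutes/day after dehorning")
print(f"difference-in-differences {contrast.did:+.4f} (p = {contrast.did_p:.3g})")

post = {"control": [], "meloxicam": []}
for w in cohort.weights:
    post[w.treatment].append(adg(w)[1])
res = compare_groups_anova(post["meloxicam"], post["control"])
print(f"\nADG post-dehorning: meloxicam {np.mean(post['meloxicam']):.2f} "
      f"vs control {np.mean(post['control']):.2f} kg/day "
      f"(ANOVA F = {res.statistic:.2f}, p = {res.p_value:.3f})")
print(
    "\nThe control arm loses lying time after dehorning while the treated"
    "\narm is flat, and treated calves keep gaining weight - the behavioral"
    "\nand performance signature the cohort generator encodes."
)
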