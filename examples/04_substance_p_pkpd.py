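"""Substance P endpoints: treatment contrast and exposure-response.

The geometric-mean ratio contrasts post-dose plasma substance P between
arms on the log scale; the log10-log10 regression relates each treated
animal's percent change from baseline to its simultaneous meloxicam
concentration.
"""

import numpy as np

from calfpkpd import (
    EndpointSeries,
    StudyConfig,
    generate_cohort,
    geometric_mean_ratio,
    loglog_regression,
    percent_change_from_baseline,
)

cfg = StudyConfig(seed=1)
cohort = generate_cohort(cfg, include=("sp", "pk"))

gm = {"control": [], "meloxicam": []}
for s in cohort.sp:
    post = np.asarray(s.values[1:])
    gm[s.treatment].append(float(np.exp(np.mean(np.log(post)))))

contrast = geometric_mean_ratio(gm["meloxicam"], gm["control"])
print(f"SP geometric-mean ratio (treated / control): {contrast.ratio:.2f} "
      f"(95% CI {contrast.ci95[0]:.2f} to {contrast.ci95[1]:.2f})")

# pair each treated animal's SP percent change with its drug level
drug = {p.subject_id: p for p in cohort.pk_profiles}
xs, ys = [], []
for s in cohort.sp:
    if s.treatment != "meloxicam":
        continue
    pct = percent_change_from_baseline(s)
    p = drug[s.subject_id]
    for i, t in enumerate(s.times_h):
        if i == s.baseline_index:
            continue
        j = np.flatnonzero(p.times_h == t)
        if len(j) == 1 and not p.bloq[j[0]] and pct.values[i] > 0:
            xs.append(p.concentrations[j[0]])
            ys.append(pct.values[i])

fit = loglog_regression(xs, ys)
print(f"log10(SP % change) = {fit.intercept:.3f} + {fit.slope:.3f} * log10(meloxicam)"
      f"   (r^2 = {fit.r_squared:.2f}, n = {fit.n_points})")
print(
    "\nA ratio near 0.5 reproduces the configured halving of SP under"
    "\ntreatment; the regression slope on simulated data is uninformative"
    "\n(SP is generated independently of drug level) - the estimator itself"
    "\nrecovers a generating line exactly, as the test suite checks."
)
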