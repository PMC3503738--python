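"""Fit the two-compartment IV-bolus model per animal and summarize.

A noise-free cohort is generated around the published population means,
each animal is fitted by weighted nonlinear least squares (1- and
2-compartment candidates, AIC selection), and the per-animal results
are averaged into the 12-row population table.
"""

from calfpkpd import (
    DoseRegimen,
    StudyConfig,
    fit_compartmental,
    generate_cohort,
    select_model,
    summarize_population,
)

cfg = StudyConfig(seed=1, residual_cv=0.0, pk_bsv_cv=0.20)
cohort = generate_cohort(cfg, include=("pk",))
dose = DoseRegimen(dose_per_kg=cfg.dose_per_kg)

fits = []
for profile in cohort.pk_profiles:
    if profile.treatment != "meloxicam":
        continue  # control animals are entirely below the LOQ
    candidates = [fit_compartmental(profile, dose, n_compartments=nc) for nc in (1, 2)]
    best = select_model(candidates)
    fits.append(best)
    print(
        f"{profile.subject_id}: selected {best.n_params // 2}-compartment "
        f"(AIC 1-comp {candidates[0].aic:8.2f}, 2-comp {candidates[1].aic:8.2f})"
    )

summary = summarize_population(fits, dose)
print(f"\npopulation summary over {summary.n_animals} animals (mean, SE):")
print(summary.table.round(4).to_string())
print(
    "\nWith no residual noise the bi-exponential data always select the"
    "\n2-compartment model; means vary around the population values only"
    "\nthrough the 20% between-animal lognormal variability."
)
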