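# Methods

## Disposition model and parameter conventions

The package's canonical units are hours, µg/mL, mL/kg and µg/kg; every
volume and clearance is normalised to bodyweight, and the 0.5 mg/kg
label dose is converted to 500 µg/kg once at the boundary
(`DoseRegimen`). The canonical parameterization is the micro-rate set
(Vc, k10, k12, k21); the clearance family (Vc, CL, CLD2, V2) and the
macro constants (A, B, α, β) are exact views converted on demand, so no
parameter set can drift out of sync. `k12 = 0` is tolerated as the
mono-exponential limit of the two-compartment model (the clearance view
is then undefined because V2 = 0 and is refused). The repeated-root
degeneracy α = β — possible only at k12 = 0 with k10 = k21 — raises an
error rather than switching to the `t·e^(−αt)` solution: it cannot
arise from distinct positive rate constants within floating tolerance
and supporting it would complicate every downstream formula for a case
the analysis never encounters.

α is computed as the larger quadratic root and β as the companion root
`k10·k21/α`, which is numerically stable when the phases are widely
separated; the interlacing property α > k21 > β holds for all positive
parameters and is property-tested against brute-force root finding.

## Per-animal fitting

Fitting minimises the weighted residual sum of squares
Σ wᵢ(Cᵢ − Ĉᵢ)² with uniform weights by default; 1/y and 1/y² are
selectable because published analyses of this kind rarely state the
scheme used, and on noise-free data all schemes share the exact
minimiser (tested). Samples below the 0.025 µg/mL limit of
quantification and the pre-dose t = 0 sample are excluded before
fitting — standard practice for an IV bolus, where the t = 0 draw
precedes the dose.

Positivity is enforced by optimising the logarithms of the parameters.
The solver is trust-region-reflective least squares with log-parameter
bounds of ±25 (i.e. every rate and volume confined to (e⁻²⁵, e²⁵), far
outside any physiologic value): the bounds exist purely so that
pathological noisy replicates cannot drive `exp` under- or overflow.
Relative tolerances are 10⁻¹², the iteration cap 500; on noise-free
data generated at the study schedule the fit recovers generating
parameters to well within the 0.1% contract, usually to machine
precision.

Initial estimates come from curve stripping (method of residuals): a
log-linear regression on the last 4 quantifiable points gives (B, β),
and the log of the positive residuals of the earlier points against the
terminal line gives (A, α). When the residuals cannot support an α
phase (effectively mono-exponential data) the fallback keeps the
β-phase estimates, assigns A from the surplus of the first observation
over the terminal line (≈ 0 for truly mono-exponential data) and sets
α = 10β as a benign starting slope.

Model selection uses the `n·ln(WRSS) + 2p` / `n·ln(WRSS) + p·ln(n)`
forms of AIC and SBC. These omit the additive constants of the Gaussian
log-likelihood, so values are comparable only between fits to the same
points and weights — which is exactly how they are used (1- vs
2-compartment per animal, lowest AIC wins, ties broken by parsimony
then SBC). A perfect fit (WRSS = 0) is flagged with a −∞ sentinel and
always preferred. The population summary averages per-animal values —
including derived parameters computed per animal first — and reports
SE = SD/√n, matching how such tables are published; consequently the
printed means of different parameter families need not satisfy the
model's algebraic identities jointly, and the package never mixes
families when constructing parameter sets from summary tables.

## Non-compartmental analysis

Cmax/Tmax are read directly off the observations with ties broken by
the earliest time. AUC/AUEC uses the linear trapezoidal rule with both
bounds required to coincide with sampled times — no extrapolation — and
segment areas accumulated with compensated summation so that splitting
an interval at an interior sample is exactly additive. Cortisol AUEC is
computed on raw concentrations with no baseline subtraction over a
configurable window; the default window is the full 0–52 h sampling
span, whose magnitude (mean concentration × 3120 min) matches the scale
on which such summaries are reported. Group tests are two-group one-way
ANOVA (identical to the pooled two-sample t test, F = t², which is
cross-checked) for Cmax/AUEC/ADG and Kruskal–Wallis with mid-rank tie
correction for Tmax, with the degenerate conventions F = 0, p = 1 for
identical zero-variance groups and H = 0, p = 1 for all-identical data.

## Endpoint statistics

Percent change from baseline is `100·(value − baseline)/baseline`
against the pre-dose sample and is scale-invariant. The
exposure–response regression is ordinary least squares of log10(percent
change) on log10(drug concentration) — base 10 to match the
conventional reporting scale — with a t-based 95% CI on the slope.
Pairs enter only when the same animal has a quantifiable drug
concentration and a strictly positive percent change at that timepoint;
non-positive changes have no logarithm, are excluded, and are counted
in the run log. Only treated animals can contribute (controls have no
quantifiable drug).

The treatment contrast on substance P is a geometric-mean ratio:
`exp(mean ln a − mean ln b)` with a pooled-variance t interval
back-transformed from the natural-log scale. Using per-animal geometric
means of the post-dose samples as the unit of analysis keeps the calf
as the experimental unit.

Lying behavior is aggregated from 5-second accelerometer epochs (720
per hour) into hourly lying/standing/walking counts; windows are 48 h
pre- and 168 h post-dehorning, and hours with human intervention are
excluded identically in both arms via configuration. The pooled lying
proportion is total lying epochs over total classified epochs — the
epoch-weighted average of hourly proportions. The pre/post contrast
uses two-proportion z tests on pooled counts within each arm and a
difference-in-differences with a normal approximation between arms.
This deliberately replaces the mixed-effects logistic regression (with
calf and pen random effects) used in trial practice: pooling epochs
overstates the effective sample size relative to a per-calf random
effect, so the p-values are anticonservative and should be read as
descriptive. The same caveat applies to the simplified t-contrasts
replacing repeated-measures mixed models for the biomarkers. A drop in
lying proportion converts to extra standing minutes per day as
`(p_pre − p_post)·1440`, rounded to the nearest minute for reporting.

Average daily gain is `(pre − arrival)/days_pre` and
`(post − pre)/days_post` per calf (19 and 10 days by default), compared
across arms by the two-group ANOVA. Heart-rate series (15-s sampling)
are reduced to per-calf window means with missing samples skipped,
then group mean ± SE; a calf with an empty window is excluded from that
window with a warning.

## Synthetic cohorts

The generator reproduces the study design: 2n calves (n = 6 per arm by
default) ranked by arrival weight, blocked in consecutive pairs, and
randomized within pair by independent uniform draws (higher draw →
meloxicam), so arms are exactly balanced and weight-matched. Every
endpoint draws from a dedicated `(stream, animal)` substream spawned
from the master seed, making cohorts bit-reproducible and insensitive
to which endpoints are generated.

- **PK.** Per-animal clearance-family parameters are lognormal around
  the population means (Vc 94.88 mL/kg, CL 6.64 mL/h/kg, CLD2
  225.18 mL/h/kg, V2 99.07 mL/kg) with a mean-preserving 20% CV —
  chosen to be consistent with the reported standard errors (SE·√6) —
  and drawn independently, since between-animal parameter correlations
  are unknowable from summary tables. Concentrations are the model
  prediction times `(1 + ε)`, ε ~ N(0, 0.15), clipped at zero and
  censored at the 0.025 µg/mL LOQ; the t = 0 sample is pre-dose and
  zero. Controls are entirely BLOQ.
- **Cortisol.** Baseline 30 nmol/L plus a log-Gaussian-in-time pulse
  peaking at 160 nmol/L around 17.5 min (inside the reported 10–30 min
  peak window) with unit log-width, identical in both arms (the trial
  found no treatment effect), with 20% lognormal noise. Any smooth
  unimodal pulse meeting the peak-window constraint would do; the shape
  is configuration, not science.
- **Substance P.** Stationary lognormal values (no time trend), control
  geometric mean 114.7 pg/mL, treated arm multiplied by the configured
  ratio 0.5, CV 40% (consistent with the reported SEM of ≈ 21 pg/mL at
  n = 6).
- **Heart rate.** 15-s samples over ±48 h: pre-dehorning mean 91 bpm, a
  +12 bpm step over 0–6 h and +3 bpm over 6–12 h, a −6 bpm treated-arm
  reduction over hours 7–11 (covering the reported 8 h and 10 h
  differences), Gaussian noise SD 8 bpm and 2% missingness.
- **Behavior.** Hourly lying counts are Binomial(720, p) with p =
  0.461→0.427 (control pre→post) and 0.431→0.430 (treated); a
  `sample_epochs=False` switch makes counts deterministic
  (round(720·p)) so noise-off inversion is exactly testable. Non-lying
  epochs split binomially into walking (10%) and standing. A dropout
  flag removes one treated calf's records, emulating accelerometer
  failure; it defaults off because that loss was accidental, not
  design.
- **Weights.** Arrival ~ N(170, 15) kg clipped to the enrolment range
  140–205 kg; pre-dehorning ADG ~ N(0.9, 0.2) kg/day over 19 days;
  post-dehorning ADG N(1.05, 0.32) treated vs N(0.40, 0.61) control
  over 10 days (SDs taken as the reported SEMs scaled by √6).

What the simulations do **not** emulate: within-animal correlation over
time in the biomarkers, circadian rhythm in behavior and heart rate,
correlation between PK parameters, assay-specific error structure, and
any mechanistic link from drug concentration to substance P (the
endpoints are generated marginally at the reported effect sizes).
Passing recovery tests therefore demonstrates that the estimators
recover what the generator encodes under the study's design and noise
levels — not that they would reproduce a real trial's raw-data
estimates.

## Problem sizes and numerical checks

The test suite runs the stochastic recovery checks at 200 seeded
replicates (the Monte-Carlo contracts are stated as within 3 MC
standard errors), the noise-free fit round trip at 30 random parameter
sets constrained to kinetics the 12-point sampling schedule can resolve
(phase separation α/β > 10), and dense-grid trapezoid-versus-analytic
AUC agreement at 0.1%. Exact-identity contracts (parameter round trips,
Vieta's identities, AUC additivity, F = t²) are tested at relative
tolerances of 10⁻⁹–10⁻¹⁴. CSV writers use 17-significant-digit
formatting and readers re-parse with correctly rounded conversion so
write→read round trips are bit-exact, which in turn makes pipeline
outputs byte-reproducible from config + seed.
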