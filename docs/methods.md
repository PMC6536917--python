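# Methods

## The task and its geometry

The triangle-completion task probes path integration: a participant is guided
along two legs of a triangle (cone 1 → cone 2 → cone 3) inside a square
tracked space and must walk, unguided, back to the remembered location of
cone 1. The tracked space is 3.5 × 3.5 m with the origin at its centre; a
return path straying more than 30 cm beyond a wall marks the trial as
excluded ("out of border"). A session comprises 27 trials — 9 in each of
three visually distinct environments, with three return conditions (no
change, boundary cues removed, surface detail removed) each appearing
exactly three times per environment in a seeded pseudo-random order.

Cone layouts are sampled by rejection: cone 1 uniform in the arena shrunk by
a placement margin, each leg length uniform in a configured range, and the
turn at cone 2 (rotation away from straight ahead) uniform in a configured
range, with all cones required to stay inside the shrunk arena. The source
study does not state the leg-length or turn bounds, so these are package
defaults chosen once: legs 1.5–3.0 m, turns 50–120°, placement margin
0.10 m. They were picked so that triangles fill the arena the way the
published exclusion statistics imply — long return legs passing close to the
walls — which is the only configuration under which a realistic noisy walker
reproduces an exclusion fraction near one third (see *Calibration* below).
Shorter-leg defaults keep almost every return path interior and cap the
attainable exclusion rate at roughly 13%.

The out-of-border test uses per-axis excess beyond the square with a strict
inequality at exactly 0.30 m: the hardware showed a warning at that distance,
and the analysis treats any crossing as exclusion of the trial. The flag is
monotone in the margin (enlarging the margin never flags a previously clean
path), which the property suite checks.

## Outcome measures

Three measures score the return leg; their identity points are mutually
consistent (a noise-free unit-gain agent scores 0 / 1 / 1):

* **Absolute distance error** (m): Euclidean distance between the logged
  response and the true cone 1. Primary outcome.
* **Proportional angular error**: unsigned rotation performed at cone 3
  (from the incoming heading to the response direction) divided by the
  optimal rotation (toward cone 1). Undefined when the optimal turn is below
  a 5° floor, which guards the ratio against blow-up on nearly-straight
  returns; such trials are dropped from angular analyses only.
* **Proportional linear error**: Euclidean distance travelled from cone 3 to
  the response divided by the required distance to cone 1 (< 1 undershoot).

Ratios (performed/optimal, travelled/required) are the primary encoding; a
folded magnitude |ratio − 1| is emitted as a secondary column because group
analyses of *accuracy* may reasonably ignore direction. Participant
aggregates are unweighted means over viable trials; no winsorizing.

Absolute distance error scales linearly under coordinate scaling while both
proportional measures are scale-invariant — the decomposition separates the
metric and directional components of the homing vector, and the generator's
noise channels map onto it cleanly (distance noise moves the linear ratio
and leaves the angular distribution untouched; tested).

## The synthetic cohort

No participant data are distributed with the study, so the cohort is a
simulation designed to exhibit the statistical relationships the analysis
chain assumes. Each participant is a noisy path integrator with four
parameters drawn from group-level means plus Gaussian between-participant
dispersion:

| parameter | meaning | HC | MCI− | MCI+ | MCI-unk | between-SD |
|---|---|---|---|---|---|---|
| heading noise SD (°) | rotation noise at cone 3 | 25 | 25 | 25 | 25 | 4 |
| distance gain | mean multiplicative gain on required distance | 0.80 | 0.78 | 0.55 | 0.68 | 0.08 |
| distance noise CV | lognormal (mean-one) distance noise | 0.40 | 0.42 | 0.70 | 0.52 | 0.08 |
| wander SD (m/step) | lateral random walk at 0.05 m steps | 0.19 | 0.20 | 0.24 | 0.21 | 0.02 |

Group separation is deliberately confined to the distance (linear) channel —
the biomarker-positive group walks with lower gain and much larger distance
noise — matching the empirical finding that biomarker-positive patients are
impaired specifically in distance estimation while rotation accuracy is
spared. Angular parameters are identical across groups. A gain below one for
everyone reproduces the undershoot bias that a small tracked space imposes.

Covariates (age, sex, education, ACE-R, NART errors) are drawn from normals
matching the published group demographics; ACE-R is capped at 100. CSF
amyloid-β and total tau come from lognormals centred on opposite sides of
the clinical thresholds (positive: median 420 / 560 pg/ml; negative: 820 /
240 pg/ml), redrawn until the drawn values classify to the intended label
under the conjunction rule (amyloid < 550 **and** tau > 375 **and**
tau/amyloid > 0.8); the stored label therefore always round-trips through
the classifier. p-tau is generated for schema completeness and unused. A
disjunction variant of the rule is available by flag since the source is
ambiguous about whether all three criteria were required jointly.

ROI volumes (EC, alEC, pmEC, hippocampus, PCC, isthmus; hemisphere-averaged,
ICV-normalized) are synthetic: literature-plausible means/SDs — no volumes
are printed in the source — with group atrophy shifts (strongest in EC and
hippocampus for the biomarker-positive group, none in the isthmus) and, for
EC and pmEC only, an explicit correlation ρ (default −0.5) between the
standardized volume and the participant's realized mean error.

### Calibration

The free generator parameters were set in a single pass before the test
suite was written, then frozen:

* the realized out-of-border exclusion fraction lands in the 25–40% band
  around the empirical 33.77% (the unit suite asserts the band; the worked
  example prints ~31%), balanced across groups;
* mean absolute errors sit near 1.4 m (HC/MCI−) and 1.8 m (MCI+) — a
  biomarker contrast of roughly 0.4 m, smaller than the published ≈ 0.98 m
  because the 3.5 m arena truncates how wrong an undershooting response can
  be — with cross-validated AUCs (see the worked example and acceptance
  output) in the published regime.

What the generator does **not** emulate: practice and learning effects,
fatigue across trials, re-entry behaviour after a boundary warning,
non-Gaussian covariate shapes, missing MRI subsets, and any causal link
between CSF values and behaviour beyond group membership (within a group,
CSF is independent of performance; across the stratified patients the
group difference induces the tau/amyloid–error associations). Passing
calibration tests therefore shows the *analysis chain* behaves correctly on
data with this structure — not that the generator is a faithful model of
patients.

## Group inference

Trial-level contrasts use a linear mixed model fit by REML (statsmodels
`MixedLM`): response ~ diagnosis × return-condition + age + sex + education
+ ACE-R + NART + environment, with a per-participant random intercept and
random coefficients over the environment factor (unstructured 3 × 3
covariance over `[1, env2, env3]`). On a singular or ill-conditioned
random-effects covariance the model refits with a diagonal structure, then
with a random intercept only, each fallback logged in the fit's notes; a fit
whose fixed-effect variances exceed 10⁴ × the response variance is flagged
non-converged. Covariates constant within a contrast subset (e.g. sex in a
nearly single-sex subgroup) are dropped with a note rather than left to
singularize the design.

Denominator degrees of freedom use the Satterthwaite approximation computed
here by moment matching: for a contrast c, df = 2g²/(∇g′ A ∇g) with
g(θ) = c′ Cov(β̂)(θ) c, θ the REML variance parameters (vech of the
random-effects covariance plus the residual variance), and A the inverse
negative Hessian of the REML log-likelihood — all derivatives numerical
(central differences, steps 10⁻⁴ relative). The df are clipped to
[1, residual df]; a residual-df method is selectable for speed. On
clustered Gaussian data matching the model's assumptions the machinery
recovers injected effects within their standard errors, the
between-participant contrast lands far below the trial-level residual df,
and the REML pieces reduce to OLS exactly at zero variance components (all
in the test suite).

On *generator* cohorts the contrast test is mildly conservative (the
acceptance suite measures its null rejection rate, which falls a point or
two short of the nominal 5%): the agents' multiplicative distance noise makes cluster
variances heterogeneous and the exclusion rule ties cluster size to agent
noise, both violations of the homoscedastic LME. This is a property of
fitting the prescribed model to realistic data, documented rather than
patched; the generator is not adjusted to hide it.

The CSF model regresses the per-participant mean error on z-scored tau and
amyloid plus age, sex and education in the biomarker-stratified patients
(OLS — one observation per participant), optionally comparing a tau ×
amyloid interaction by likelihood ratio. ANCOVA utilities (with a
rank-transform option) and Kruskal–Wallis / Mann–Whitney fallbacks cover the
demographic comparisons; Bonferroni adjustment across a family of m
comparisons is applied by the caller as α/m.

## Volumetry associations

Each ROI is tested in its own OLS model: mean error ~ normalized volume +
age + sex + education + group-mean performance, the last being the
participant group's mean error assigned to every member — an unusual
adjustment, implemented literally as specified upstream. The
backward-stepwise search runs three phases: (1) deletion-only AIC descent
(drop whichever candidate lowers AIC most; AIC ties broken by dropping the
larger-p predictor; AIC is non-increasing by construction and terminates in
at most as many steps as there are candidates); (2) VIF pruning, recomputing
all VIFs after every single drop and removing the worst offender above 10;
(3) Benjamini–Hochberg at α = 0.01 over all final-model coefficients except
the intercept — the multiple-comparison family is the final model, not just
the ROI survivors — reporting the candidates that pass. Forced covariates
(group, age, sex, education) are never deleted. A start
with p ≥ n is tolerated: the initial AIC is computed from a tiny-ridge fit
(α = 10⁻⁶) and logged, since deletion-only search only needs a ranking until
the design becomes overdetermined; the final model must be full rank or the
procedure fails listing the collinear set.

## Diagnostic classification

"Linear classification adjusted for age, sex and education" is implemented
as logistic regression (standardized features, C = 100, effectively
maximum-likelihood with a mild guard against separation) on (mean outcome
measure, age, sex, education); linear discriminant analysis is available by
flag since the source does not name the classifier. Folds are stratified
10-fold — stratification is not stated in the source but with 12-vs-14
classes unstratified folds can lose a class entirely, so it is imposed and
documented. Each participant is scored exactly once by a model never trained
on them; the empirical ROC over the out-of-fold posteriors handles ties as
diagonal segments, so the trapezoid AUC equals the normalized Mann–Whitney
U with ties counted one half (verified exactly against brute force). The
operating point maximizes Youden's J with ties broken toward higher
specificity, and is additionally reported as a cut on the raw error scale
(cm).

Confidence intervals bootstrap *participants* (stratified within class, so
no replicate loses a class) and re-run the entire cross-validation inside
each of the 1000 replicates — the conservative reading of an ambiguous
ordering of bootstrap and CV — taking percentile 2.5/97.5 bounds for the AUC
and for TPR on a fixed FPR grid.

## Numerical and design choices

* All randomness derives from one master seed through named `SeedSequence`
  substreams (geometry, agents, covariates, CSF, volumes; classification and
  bootstrap in the pipeline), so any stage reruns bit-identically.
* Degenerate triangles (collinear within 10⁻⁹ m) raise instead of returning
  garbage angles; the angular floor is 5°; required return distances below
  10⁻⁹ m are rejected.
* Files store metres; human-readable report text uses centimetres.
* The simulated return path is discretized at 0.05 m with an exact final
  partial step, so a noise-free agent lands on cone 1 to machine precision.
* Monte-Carlo test sizes (150 null replicates for calibration, 30 for
  stepwise retention, 12-cohort ladders for monotonicity) were chosen to
  keep each property's sampling error well inside the asserted bands.

## Known limitations

* The arena truncates large errors, compressing group contrasts relative to
  the published centimetre effects; contrasts here validate recovery and
  calibration, not the published magnitudes.
* The 2295-trial ledger implies 85 × 27 contributing sessions although 86
  participants are described; the generator takes the group sizes literally
  (86 × 27 = 2322 administered), and the published ledger is reproduced as a
  separate deterministic accounting check.
* Satterthwaite df are approximate under the generator's heteroscedastic
  clusters (conservative by a few points of type-I error at n = 26).
* The stepwise search, like its empirical counterpart, is vulnerable to
  collinearity among ROI columns; VIF pruning mitigates but does not remove
  interpretation risk.
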