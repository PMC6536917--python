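# pathint

Analysis pipeline for immersive-VR **triangle-completion path integration**
as an early marker of Alzheimer's disease. Participants walk two guided legs
of a triangle in a small tracked space and must return, unguided, to the
remembered start; the accuracy of that homing response — and its
decomposition into rotation and distance components — separates mild
cognitive impairment (MCI) patients with a positive CSF Alzheimer's
biomarker profile (MCI+) from biomarker-negative patients (MCI−) and from
healthy controls (HC).

The package is written for quantitative researchers in spatial cognition and
clinical biostatistics who want to study, extend or stress-test this
analysis chain without access to patient data: a synthetic agent-based
cohort generator stands in for the study population, and every downstream
stage operates on ordinary CSV tables.

## What it computes

For each trial with cones c₁, c₂, c₃ and response r̂:

* absolute distance error ‖r̂ − c₁‖ (primary outcome, metres);
* proportional angular error: performed rotation at c₃ / optimal rotation,
  where the optimal turn is the angle from heading (c₃ − c₂) to
  (c₁ − c₃);
* proportional linear error: ‖r̂ − c₃‖ / ‖c₁ − c₃‖.

Downstream, per study design:

* **Mixed-effects contrasts** (REML, Satterthwaite df): outcome ~ diagnosis
  × return-condition + age + sex + education + ACE-R + NART + environment,
  random intercept per participant and environment random coefficients.
* **CSF model**: mean error ~ z(tau) + z(amyloid-β) + covariates in the
  biomarker-stratified patients.
* **Volumetry**: per-ROI regressions of error on ICV-normalized volumes
  (EC, alEC, pmEC, hippocampus, PCC, isthmus) and a backward-stepwise
  search (AIC deletion → VIF pruning → Benjamini–Hochberg FDR).
* **Diagnostics**: stratified 10-fold cross-validated linear classification,
  ROC/AUC (provably equal to the tie-corrected Mann–Whitney statistic), the
  Youden-optimal operating point, and participant-level bootstrap CIs
  (1000 replicates, CV re-run inside each).

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
synthetic cohort of 86 participants (41 HC, 14 MCI−, 12 MCI+, 19 without
CSF data), 27 trials each:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/03_group_inference.py
python analysis/05_classification.py
```

prints (seed 0, abridged):

```
participants: 86
administered trials: 2322
excluded out-of-border: 719 (30.96%)
viable trials: 1603

mean absolute distance error by group (m):
HC             1.389
MCI_neg        1.432
MCI_pos        1.792
MCI_unknown    1.527

mci_vs_hc  abs_error_m  dx =   21.16 +/-  8.21 cm (df 224, p 0.0106)
pos_vs_neg abs_error_m  dx =   40.28 +/- 12.27 cm (df 60, p 0.0017)
pos_vs_neg prop_linear  dx =   -0.23 +/-  0.05    (df 55, p 0.0000)
pos_vs_neg prop_angular dx =    0.02 +/-  0.04    (df 35, p 0.7040)

CSF model on 26 stratified patients: R^2 = 0.651

mci_vs_hc: AUC 0.808 [0.701, 0.900] (n=86); errors >= 141 cm -> sensitivity 0.80, specificity 0.61
pos_vs_neg: AUC 0.774 [0.667, 1.000] (n=26); errors >= 169 cm -> sensitivity 0.83, specificity 0.86
```

and `analysis/04_volumetry.py`:

```
per-ROI regressions (Bonferroni-adjusted alpha 0.0083):
  EC           slope     -795.3  p 0.0003 *
  alEC         slope      360.2  p 0.5658
  pmEC         slope    -2677.5  p 0.0011 *
  hippocampus  slope        7.6  p 0.9060
  PCC          slope        0.0  p 0.9995
  isthmus      slope      -35.1  p 0.6385

backward stepwise: R^2 = 0.555, surviving FDR: ['nvol_EC', 'nvol_pmEC']
```

Read: roughly a third of trials leave the tracked space and are excluded;
the biomarker-positive group homes ~40 cm worse than the biomarker-negative
group and the deficit sits in the **distance** component (proportional
linear error down 0.23, angular unchanged); entorhinal and posteromedial
entorhinal volumes — and only those — predict homing error; MCI+ vs MCI−
classifies well with a wide small-sample CI. That structure —
linear-channel impairment, entorhinal-led volumetry, high MCI+/MCI−
discriminability — is the empirical study's fingerprint.

The same machinery is scriptable as a CLI
(`pathint simulate|score|analyze|volumetry|classify|all --config config.yaml
--seed N --out DIR`) or as a library (`pathint.generate_cohort`,
`pathint.fit_lme`, `pathint.bootstrap_roc`, ...). Every output is
reproducible bit-for-bit from the master seed recorded in the run manifest.

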