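# Methods

This note documents the models, defaults and numerical choices behind
`ploidyrisk`, and what the synthetic-data experiments do and do not show.

## 1. The measurement model

DNA image cytometry measures, per nucleus, the integrated optical density
(IOD) of Feulgen-stained chromatin, proportional to DNA content. Nuclei
are classified into epithelial cells, internal controls (lymphocytes,
fibroblasts — normal 2c DNA) and debris; cut, overlapped and pyknotic
nuclei are discarded at gallery editing. A sample contributes up to 3000
nuclei; at least 300 retained epithelial nuclei are required for a
diagnosis.

### Synthetic nucleus tables (`ploidyrisk.nuclei`)

The generator emulates the measured feature level, not images:

- Every stemline (clonal population with DNA index `di`) contributes a
  G0/G1 peak at `c = 2·di`, a G2 peak at `4·di` and a uniform S-phase
  plateau between them. Peaks are **Gaussian in IOD with SD = CV·mean**;
  no distributional form is canonical for densitometry peaks, but the CV
  is the field's own width metric and a Gaussian is the standard reading.
  Default within-stemline cycling fractions are 5% G2 and 5% S.
- Internal controls sit at 2c with their own CV (default 2%). Lymphocytes
  and fibroblasts share one distribution: their counts differ between
  preparation methods in real data, but their DNA content does not.
- A configurable fraction of epithelial nuclei is placed uniformly on
  c ∈ (5, 9], emulating rare supra-tetraploid events.
- Debris is sub-1c (uniform on (0, 0.8c]); artifacts are epithelial-like
  with distorted IODs (cut: halved; overlapped: doubled; pyknotic:
  spread compressed to 20%).
- Counts per component use largest-remainder apportionment, so configured
  fractions are hit exactly; all randomness flows from one seed per
  sample.

The G1 coefficient of variation defaults to 2.5% and is constrained to
[1, 5]%: 5% is the diagnostic QC ceiling, and observed diploid-peak CVs
in routine material span roughly 1.3–3.8%.

What the generator does **not** model: stain and illumination drift,
nuclear segmentation error beyond the three artifact classes, spatial
heterogeneity within a lesion, and debris overlapping the epithelial
range. Classifier recovery on this generator therefore demonstrates that
the rule cascade is implemented correctly and is robust to sampling noise
— not that it would reach the same accuracy on arbitrary clinical
material.

## 2. The ploidy classifier (`ploidyrisk.ploidy`)

**Normalisation.** The 2c reference is the 5%-trimmed mean IOD of the
modal control cluster (controls within ±25% of the kernel-density mode),
robust against debris misclassified as control; at least 30 artifact-free
controls are required. Every retained epithelial nucleus gets
`c = IOD × 2 / reference`. Because the reference scales linearly with the
data, the diagnosis is invariant to rescaling all IODs by any k > 0
(property-tested).

**Peak detection.** Gaussian KDE over the c-values with a Silverman
bandwidth floored at 0.05c (the floor keeps near-degenerate histograms
from producing needle artifacts). Candidate modes are local maxima with
prominence ≥5% of the maximum density **and** a full width at half the
absolute peak height of at most 0.4·mode. The width gate is what
distinguishes a stemline peak from a broad plateau: diagnostic peaks are
narrow by construction (the CV ≤ 5% QC gate bounds their width), while a
flat or slowly varying density has shallow local maxima whose
half-height width spans most of the range. Each nucleus is then assigned
to the nearest surviving mode within ±10% of the mode position (matching
the width of the DI windows in the diagnostic criteria), and a stemline
peak is any mode whose assigned fraction strictly exceeds 10%. Fractions
need not sum to 1 — S-phase and scatter stay unassigned.

**Rule cascade.** Applied in order, every fired rule recorded:

1. *inadequate*: n < 300, or diploid-peak CV > 5% (when no DI ∈ [0.9, 1.1]
   peak exists the CV of the largest peak is used and flagged — the QC
   question still applies to a pure aneuploid shift).
2. *aneuploid*: any supra-threshold peak with DI outside [0.9, 1.1] and
   outside [1.8, 2.2], or 5c exceeding rate > 1% (exact count, strict).
3. *tetraploid*: a supra-threshold peak with DI ∈ [1.9, 2.1], no other
   abnormality (guaranteed by rule order).
4. *diploid*: exactly one G0/G1 peak, 4c-band (c ∈ [3.6, 4.4]) fraction
   ≤ 10%, 5cER ≤ 1%.

All thresholds are strict inequalities; ties fall to the less abnormal
side. Three situations are not covered by the printed criteria and are
resolved as package policy, each with its own reason code:

- a supra-threshold peak with DI in [1.8, 2.2] but outside [1.9, 2.1] is
  neither aneuploid (the G2 exemption covers it) nor tetraploid by the
  letter of the windows; it is classified tetraploid with a `rule_gap`
  flag, since the G2 exemption signals the band is treated as
  non-aneuploid;
- a 4c-band fraction > 10% without a discrete 4c mode is classified
  tetraploid with a flag;
- no supra-threshold G1 structure at all (or two modes inside the diploid
  window) yields *inadequate*: such a histogram is not interpretable
  under the criteria.

The 9c exceeding rate is computed and reported but plays no role in
classification. The 5c rate counts all retained epithelial nuclei above
5c with no exemption for aneuploid-stemline G2 nuclei — a deliberate
reading; it makes high-DI stemlines (e.g. DI 1.8 with cycling fraction)
aneuploid through their G2/S tail, which is the direction the criteria
intend.

**Recovery experiment** (`ploidyrisk.evaluation`). A grid of 20 clearly
separated configurations (aneuploid stemlines at DI 1.2–1.8 with
fractions 0.15/0.30, >5c excess 2–4%, tetraploid stemlines with quiet
>5c tails, pure diploid; G1 CV 2% and 4%) × 11 seeds, n = 1200 nuclei per
sample. The expected label is derived *analytically* from the generator
parameters (population 5c rate from the mixture geometry; supra-threshold
stemline DI against the windows), never from the classifier. Recovery is
≥ 95% (measured ≈ 99%), and the one configuration whose population 5c
rate sits at ≈1.2% — inside the sampling noise of the 1% threshold at
n ≈ 700 epithelial nuclei — is tracked separately as a boundary case and
asserted to fall on one of its two admissible sides.

## 3. The cohort model (`ploidyrisk.cohort`, `pipeline`, `stats`, `model`)

### Generator

Per patient: dysplasia grade ~ a 4-category distribution (default
121:47:32:28 over none/mild/moderate/severe, the margins of the
228-patient reference cohort); ploidy ~ a row-stochastic matrix given
grade (default from the same cohort; the none-grade/aneuploid cell is a
structural zero); transformation time ~ Exponential with a per-stratum
constant hazard. Hazards may be keyed by grade (default 0.09, 0.53, 3.74
and 10.64% per person-year), by ploidy, or by (grade, ploidy); an
optional within-grade aneuploid multiplier (≈2.4 emulates the mutually
adjusted effect) scales grade-keyed hazards. Constant hazards are the
only defensible choice given that a single annual rate per stratum is
what the reference data report. Censoring is administrative, uniform on
5–9.6 years; an independent competing death from other causes runs at
0.01/yr; ages are N(55, 13.9²) clipped to [18, 95]; 25/228 of patients
receive repeat biopsies (2–7 per patient, matching the reference
multiplicity pattern) placed before the worst biopsy with grades no
worse than the patient's worst. Outcomes are clocked from the latest
biopsy so every endpoint postdates every biopsy. An
`early_transform_fraction` can force a share of events below 0.5 years
to exercise the 6-month subgrouping.

### Pipeline conventions

- *First-worst index*: earliest biopsy attaining the most abnormal result
  on the axis (none < mild < moderate < severe; diploid < tetraploid <
  aneuploid; inadequate is not a result). Same-date ties break stably by
  biopsy identifier. Selection is invariant to input order.
- *Endpoint*: earliest of carcinoma date (event), oral-carcinoma death
  (event; the death date stands in for the transformation date when no
  diagnosis date precedes it), other-cause death (censor), last follow-up
  (censor); time in years at 365.25 d/yr. An endpoint preceding the index
  is a data error.
- *6-month subgroup*: events at < 0.5 years (strict) are removed in the
  "excluding" analyses; censored patients never are.
- *Synchronous-worst exclusion*: a patient whose first-worst dysplasia
  biopsy is dated the day of the carcinoma is excluded from the
  dysplasia-axis survival/rate analyses but retained on the ploidy axis
  when a valid ploidy result exists. This is why the dysplasia axis
  carries 23 events against the ploidy axis's 24 in the reference
  pattern.
- *Tetraploid patients* (3 of 228 in the reference) are merged with
  diploid for predictive values and dropped from any Cox model containing
  a ploidy term — too few for a stable contrast.

### Statistics

- Person-time rate: `100·D/PY`; CI `rate·exp(±1.96/√D)` for D ≥ 1. The
  log-normal form reproduces the published severe-grade CI (6.18, 18.33)
  exactly; zero events report rate 0 with a null CI.
- Proportions: unclipped Wald `p ± 1.96·√(p(1−p)/n)`, which reproduces
  every published predictive-value CI including upper bounds above 100%.
  Published tables round some values and truncate others (1.3271 → 1.32);
  the package keeps full precision and tests compare at printed
  precision.
- χ²: Pearson without continuity correction; the ploidy × grade
  association is computed on the diploid+tetraploid-collapsed 2×4 table
  (df = 3, as reported) with the uncollapsed 3×4 version also available.
- Survival: lifelines (KM product-limit; multivariate log-rank with
  df = strata − 1, zero-event strata permitted; Cox with Efron ties, age
  continuous, sex binary). Univariate models adjust for age and sex;
  the multivariate model mutually adjusts grade and ploidy. Constant
  covariates are dropped with a warning; non-convergent fits surface as
  explicit errors, and the model facade records them as warnings rather
  than failing the whole analysis.
- Agreement: Cohen's κ = (p_o − p_e)/(1 − p_e) via scikit-learn, with the
  identical-vector case pinned to 1.0.

### Reference counts (`ploidyrisk.datasets`)

The published cohort's printed counts are stored as data: the
grade × ploidy patient table, per-stratum events and person-years for both
axes and subgroups. The grade × ploidy × outcome *cell* counts are not
printed anywhere; they are reconstructed — uniquely — from the printed
margins, the printed combined-test predictive values and the statements
that the transforming non-dysplastic and mildly dysplastic lesions were
not aneuploid. Every printed combination value follows from the
reconstruction, which is how it is validated.

## 4. Simulation sizes and calibration experiments

Problem sizes were chosen so each experiment has the statistical
resolution its acceptance band requires:

- *Classifier recovery*: 220 graded samples (20 configs × 11 seeds) at
  n = 1200 nuclei, ~5 s.
- *Cox HR recovery*: generator truth HR 6.8 (aneuploid vs diploid),
  n = 5000 patients per cohort with a 3%/yr diploid baseline (~1400
  events), log-HR averaged over 3 replicate cohorts. The baseline is set
  by power analysis: it makes the ±15% recovery band ≈ 3.4 standard
  errors of the averaged estimate. At the reference cohort's observed
  rates (~0.7%/yr diploid) the same band would be ≈ 1.7 SE and the
  experiment would fail ~10% of the time purely by Monte Carlo noise —
  the experiment measures estimator correctness, not cohort realism.
- *Null calibration*: 100 replicates at n = 2000 with a 4%/yr baseline
  (~480 events), so the (0.8, 1.25) band is ≈ 2.4 SE; ≥ 95% of replicates
  must fall inside.
- *Marginal recovery*: χ² goodness of fit at α = 0.01 over 20 seeds of
  n = 5000, allowing up to two rejections (the expected false-positive
  allowance); the aneuploid-given-severe conditional is checked pooled
  over 25 seeds of n = 2000 within 3 standard errors.

## 5. Known limitations

- Kaplan–Meier curve shapes, mean transformation times and the published
  hazard ratios themselves are not reproducible without the patient-level
  data; the survival stage is validated by parameter recovery and null
  calibration instead.
- The generator's exponential hazards cannot express the reported
  clustering of mild/moderate transformations in the first two years of
  follow-up.
- The classifier's peak-membership window (±10% of the mode) and the KDE
  bandwidth floor are package choices; the original diagnostic software
  does not document its peak definition. Both are recorded in every
  diagnosis for auditability.
- Repeat-biopsy patients are treated as exchangeable with single-biopsy
  patients; whether they differ in risk is unknown.
- Measured diploid-peak CVs are mildly truncated by the assignment
  window, so the CV > 5% QC gate engages for genuinely broad peaks
  (window-limited CV ceiling ≈ 5.8%); histograms that broad are already
  marginal for diagnosis.
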