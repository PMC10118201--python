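# Methods

## Data model

A cohort consists of three glycan peak tables — total plasma protein
(39 peaks), IgG (24) and IgA (30), each a samples × peaks matrix of
integrated HILIC-UPLC fluorescence areas — and a clinical table with age
(years), GDM status (control/case) and metabolic markers: fasting glucose
(mmol/L), HbA1c (mmol/mol and %), fasting insulin (pmol/L), HOMA2-IR,
HOMA2-%B, triglycerides, HDL and total cholesterol (mmol/L), total
proteins (g/L), urate and fructosamine (µmol/L), ALT/AST/GGT (U/L).
HOMA2 indices are treated as upstream-computed input columns.  Peak and
clinical tables are aligned by sample-ID intersection; order is never
assumed.  Readers accept CSV/TSV/XLSX, auto-detect decimal commas per
column, and map clinical headers through an editable alias table.

## Normalization and transforms

Peak areas are compositional: each row is scaled to percentages of its
total area (scale-invariant; degenerate all-zero rows are an error).
Percentages map to the real line by `logit(x/100)` with the proportion
clipped at ε = 1e-6 — the boundary policy for 0% peaks, preserving order
while being negligible for observed abundances.  Every variable entering
a model is rank-INT transformed: value with (tie-averaged) rank r among n
non-missing becomes Φ⁻¹((r − c)/(n − 2c + 1)) with the Blom offset
c = 3/8, the standard convention in omics association work.  Because
rank-INT is invariant under any strictly increasing per-variable map, the
logit matters only for multi-peak derived traits; traits are therefore
evaluated on the percentage scale (where ratio-of-sums has its "% of
structures" meaning) and rank-INT'd afterwards for modelling.

## Derived traits

A trait is `100 · Σ(wᵢ·GPᵢ)/Σ(wⱼ·GPⱼ)` with unit weights by default and
an optional `TOTAL` denominator (= the whole chromatogram).  Built-in
panels (plasma 16: G0–G4, S0–S4, B, CF, LB, HB, HM, A2; IgG 9: G0–G2,
S0–S2, B, CF, HM; IgA 12: G0–G3, S0–S3, B, CF, HM, A3) are
**reconstructed**: the dominant-structure annotation of every peak is
shipped as a data file, and trait membership follows from classifying
those structure strings (galactose/sialic-acid counts, bisecting GlcNAc,
core fucose, antenna count, oligomannose).  Laboratories with their own
validated trait sheets replace one text file per panel (grammar:
`TRAIT = (GP1 + 2*GP4 + …) / (… | TOTAL)`).  Design choices:
galactosylation/sialylation/bisection/fucosylation/branching are expressed
per complex-type glycans (so G- and S-families each partition to 100%, and
LB + HB = 100 exactly), while HM is per total chromatogram — the
convention that keeps oligomannose interpretable as an abundance share.
Coeluting minor structures are metadata only; traits are defined on peaks.

## Association models

For glycan variable y and marker x, ordinary least squares on complete
cases of that test:  `rank-INT(y) = α + β·rank-INT(x) + γ·age + ε`, with
age on its natural scale.  The GDM contrast rank-INT's y only:
`rank-INT(y) = α + β·I(case) + γ·age + ε`.  Inference for β uses the t
distribution with n − 3 df and Wald 95% intervals.  The default family is
all 130 glycan variables (93 peaks + 37 derived traits) × 7 markers
(fasting glucose, HbA1c mmol/mol, fasting insulin, HOMA2-IR, HOMA2-%B,
total cholesterol, triglycerides) + GDM = 1040 tests; the marker list is
configurable.  The solver is a shared multi-RHS least-squares core (one
solve per predictor across all fully-observed glycan columns, per-column
fallback under missingness), verified in tests against normal-equations
and statsmodels oracles to 1e-10.

Group descriptives use linear-interpolation quantiles and the two-sided
Wilcoxon rank-sum test in its continuity-corrected, tie-corrected normal
approximation (exact enumeration serves as the test oracle).

## Multiple testing

Glycan variables are strongly inter-correlated (compositional closure,
traits as sums of peaks, shared latent biology), so m = 1040 nominal
tests overstate the family.  The Li–Ji estimator summarizes the
correlation matrix of the rank-INT glycan variables through its
eigenvalues: `Meff_vars = Σ f(λᵢ)`, `f(λ) = I(λ ≥ 1) + (λ − ⌊λ⌋)`
(floor evaluated with a 1e-9 tolerance — an eigenvalue integer up to
round-off must not contribute a spurious fractional ~1).  Since every
predictor contributes one test per variable, `Meff_tests = Meff_vars ×
(tests per variable)`.  The BH step-up then runs with Meff_tests in the
numerator over integer ranks, reducing exactly to standard BH when
Meff = m; a literal Bonferroni-style `bonferroni_meff` mode and plain
`bh` are available behind a flag.  Pooling is one family across all
panels and predictors (per-panel families optional).

Two properties of this procedure deserve explicitness.  First, replacing
m by Meff raises the nominal FDR level to ≈ α·m₀/Meff — that is the
power-for-strictness trade the correction makes; simulations here measure
mean false-discovery proportion at its theoretical level (and plain BH
within the classical bound).  Second, at n ≪ M the sample correlation
spectrum is spread by estimation noise, deflating Meff below its
population value; with 130 variables at n = 89 the default cohort gives
Meff_vars ≈ 44 (352 effective tests of 1040) — the same order of
compression seen in published glycomics families of this shape.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with ground truth recorded:

* **Markers.**  Each sample carries latent standard-normal scores sharing
  a metabolic factor (loadings ≈ 0.25–0.6; HOMA2-IR/%B are noisy monotone
  combinations of the insulin and glucose scores, +/− respectively).
  Scores map monotonically onto per-group (Q1, median, Q3) targets by
  two-sided log-linear quantile interpolation; the shipped defaults
  describe a GDM-screening pregnancy cohort at 24–28 weeks (e.g. control
  fasting glucose 4.7 (4.5; 4.9) vs case 5.1 (4.9; 5.2) mmol/L; insulin
  43.5 (34.0; 61.3) vs 60.9 (44.3; 78.5) pmol/L), 48 controls and 41
  cases.  Group differences live entirely in the mapped values, so glycan
  variables stay exactly null for the GDM contrast unless a direct shift
  is configured.
* **Glycans.**  Per panel, peak log-weights = fixed baseline + Λ·g +
  N(0, σ²) with σ = 0.4, softmax to proportions, times a log-normal total
  area.  The latent factors g (dimension 4) induce the correlated trait
  structure the Meff correction needs; a (latent × marker) effect matrix
  B sets g = B·u + noise, making specific peaks truly associated with
  specific markers.  A logistic-normal model was chosen over Dirichlet
  precisely to control this correlation.
* **Ages** are Uniform(27, 38) years, independent of group.
* **Determinism.**  One seed feeds a spawned-stream scheme (age, markers,
  glycans, totals), so outputs are bit-identical under a fixed seed.

Not emulated: chromatographic drift, batch effects, measurement
replicates, immunoglobulin-subclass composition, and any real biological
peak-to-marker map — so passing tests certify the statistical machinery
and its calibration, not biological conclusions about real cohorts.

**Effect sizes.**  The injected "headline" effect (B entry 1.0 for
fasting insulin, inducing top-peak standardized β ≈ 0.5 at the cohort
size) is sized from the magnitude a top-ranked association in such a
family implies (adjusted p of order 1e-5 in a ~200-effective-test family
⇒ raw p ~ 2e-7 ⇒ |t| ≈ 5.6 at n = 89).  Recovery simulations use B = 0.75
(latent correlation 0.6).

## Numerical and design choices

* Quantiles: numpy linear interpolation throughout (descriptives depend
  on the convention, so it is fixed and shared).
* Complete cases per test; n is reported per row and may differ.
* Correlation for Meff: Pearson on rank-INT variables (≈ rank
  correlation), pairwise-complete; symmetric eigensolver; |λ| folds
  round-off negatives.
* Result tables serialize at 17 significant digits plus 3-significant
  display columns, and are re-read with round-trip float parsing, so
  write→read is bit-identical.
* CI coverage: with both variables rank-INT standardized, β̂ estimates a
  correlation, whose sampling sd (1 − ρ²)/√n is smaller than the model SE
  √(1 − r²)/√(n−3) by the factor √(1 − ρ²).  Wald intervals are therefore
  exactly nominal only near ρ = 0 (measured 0.950 at ρ = 0.2, n = 200)
  and grow conservative with effect size (~0.978 at ρ = 0.5, ~0.986 at
  ρ = 0.6).  They never under-cover.
* Within one family the 1040 p-values are strongly dependent, so
  uniformity under the null is checked across independent replicate
  cohorts (the valid exchangeable units), not by a single
  Kolmogorov–Smirnov test inside one family, whose null reference assumes
  independence.
* Simulation sizes in the shipped tests (5–10 cohorts for null checks,
  50–200 replicates for recovery, 500 for coverage) were chosen as the
  smallest giving stable Monte-Carlo error for each assertion.

## Known limitations

* Built-in trait panels are reconstructions from dominant-structure
  annotations; laboratory-validated panels should replace them for real
  analyses (one text file per panel).
* The Li–Ji-modified BH controls FDR at ≈ α·m₀/Meff, not α; users wanting
  the classical guarantee can set `fdr_mode: bh`.
* Mixed/hierarchical models, batch correction, BMI-adjusted sensitivity
  models and permutation-based FDR are out of scope.
* The Wilcoxon p-value uses the asymptotic approximation; for groups
  smaller than ~8 an exact method would be preferable.
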