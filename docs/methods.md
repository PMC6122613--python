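# Methods

This note records the statistical model implemented by `lungdx`, the design
choices made where the published description leaves the design open, and what
the synthetic-data experiments do and do not establish.

## Data model

A subject is a group label (cancer / inflammation / control), an optional TNM
stage (cancer only), an optional SUVmax (PET-imaged groups only), and a
110-vector of integration-region (IR) values. Raw integrals are normalized to
the total integrated area over all 110 regions, yielding relative
concentrations on the unit simplex. The region map pins the two regions with
published chemical-shift bounds — IR89 (glutamate + methionine,
2.197–2.218 ppm) and IR72 (methionine, 2.63–2.66 ppm) — and partitions the
remaining retained ranges (10.0–5.2 and 4.7–0.3 ppm, excluding water at
4.7–5.2 ppm and the TSP reference at −0.3–0.3 ppm) into equal-width
placeholder regions. Only region *indices* enter the statistics, so the
placeholder bounds are inert; region membership is half-open
[ppm_low, ppm_high) so shared boundaries are unambiguous, and spectrum
integration is trapezoidal with the intensity interpolated at region edges
(the quadrature rule is not specified in the source description; trapezoidal
is the standard choice for sampled spectra).

## Synthetic cohort generator

The study cohort is not publicly deposited, so the generator emulates its
printed statistics. Group sizes (269/108/347) and the cancer stage table
(IA 53, IB 22, IIA 16, IIB 16, IIIA 63, IIIB 28, IV 71) are matched
*exactly* — stages are assigned as deterministic counts, not multinomial
draws, so the stage structure is not a source of simulation variance.

**Positive-support sampling.** Relative concentrations and SUVmax are
non-negative with large coefficients of variation (the cancer glutamate CV is
0.98), so a normal model would place substantial mass below zero. Markers are
therefore drawn from a gamma distribution moment-matched to the printed mean
and SD (shape (μ/σ)², scale σ²/μ), which preserves both moments exactly;
σ = 0 degenerates to a constant. Higher moments are unconstrained by the
printed tables, and the gamma's right skew is a modelling choice, not an
inferred fact.

**Composition and closure.** Effect regions (IR89 plus any configured
secondary effects) are drawn on the relative scale; the remaining 107
background regions share the leftover area (1 − Σ effects) in proportion to
i.i.d. gamma draws whose parameters are identical across groups; the vector
is then scaled by a subject-level total area (gamma, mean 100, SD 10) to
produce raw integrals. Total-area normalization therefore recovers the
configured relative effect values exactly. Two consequences deserve note:

- *Physical bound.* Relative concentrations cannot exceed 1, but a gamma at
  the inflammation moments (0.485 ± 0.237) has ≈ 5% of its mass near or above
  the bound once the secondary effects are added. Subjects whose effect
  values would exhaust the total area are redrawn, which truncates that tail
  and lowers the realized inflammation-group mean by roughly 0.03 at the
  cohort level. The sampler itself is exactly moment-matched; parameter-
  recovery checks are therefore stated against the sampler's direct output,
  and cohort-level checks on the (nearly untruncated) cancer group.
- *Closure leakage.* On the simplex, the complement of IR89 sums to
  1 − IR89 exactly, so background regions cannot be literally independent of
  the class. The background CV is set high (SD/mean = 2 per region, emulating
  the spiky unassigned/lipid regions of real spectra) so that no small subset
  of background regions is a usable proxy for the glutamate signal at the
  study's sample size. This realizes the design premise that only configured
  effect regions are *learnably* informative — and it is what makes ablation
  of IR89 genuinely destructive, as observed for the real data.

**Secondary effects.** IR15 (tyrosine) and IR96 (alanine/isoleucine/lysine)
are given modest default separations (relative means 0.010/0.014/0.012 and
0.020/0.028/0.024 for cancer/inflammation/control, SDs ≈ 35–40% of the mean).
No group means are printed for these regions; the defaults encode "clearly
significant univariately, far weaker than glutamate", matching their
qualitative role.

**SUVmax dependence.** Only marginal SUVmax moments are published, so SUVmax
and glutamate are conditionally independent given the class by default; a
Gaussian-copula rank-correlation knob (`suv_glutamate_rho`) is available for
sensitivity analyses. Combined-rule outcome rates (discordance frequencies,
the headline 100%/94% sensitivities/PPVs) depend strongly on this unpublished
joint structure and are deliberately not treated as reproducible targets.

## Univariate screen

Unequal-variance (Welch) *t*-tests with Satterthwaite degrees of freedom are
used: the printed group SDs for glutamate differ by more than a factor of
1.5, making the equal-variance form indefensible. The 110 p-values are
adjusted jointly by the Benjamini–Hochberg step-up. Fold change is
mean(group b) / mean(group a), with (a, b) = (cancer, inflammation) the
conventional ordering. The volcano classes use adjusted p < 0.05 for
"significant" and |log2 FC| ≥ 1 for "high fold change"; both thresholds are
arguments, since no numeric thresholds are published for the classes.

## Classifier

**Selection.** "Top K by LASSO" is realized as the order of first entry into
the active set along the decreasing-penalty L1 least-squares path on the
±1-coded response (computed by LARS). Entry order ranks features without
committing to a single penalty value; ties are broken toward the smaller
column index, exact duplicate columns collapse onto their smallest index, and
features that never enter rank after all entrants by |inner product with the
response|. On orthonormal designs this reduces to ranking by absolute
feature–response correlation, which is the closed-form oracle used in tests.
An L1-penalized least-squares (rather than logistic) path matches the PLS
regression framing of the classifier.

**Projection and rule.** Features are autoscaled (mean 0, SD 1) on the
training partition; zero-variance columns are rejected rather than silently
dropped. PLS components are fitted to the ±1 response on the selected,
scaled features; at full rank the fit coincides with ordinary least squares,
which the tests exploit as an oracle. LDA with equal class priors (the
balanced design makes priors uninformative) is fitted on the component
scores; a point exactly on the decision boundary goes to the first class
label in sort order.

**Component count.** The number of latent components is not published. The
default "auto" picks A ∈ {1..min(8, K)} minimizing an inner stratified
4-fold MCE computed on the training partition only, with the feature
signature selected once on that partition and shared across candidates (the
held-out outer fold is never touched). A fixed integer A is accepted for
strict reproducibility studies.

**Cross-validation engine.** Per repeat: draw a majority-class subsample of
minority size without replacement, stratify the balanced set into 4 folds
(stratification keeps the 1:1 balance per fold; shuffling is seeded), and
for each fold refit scaling, selection, component choice, and PLS-LDA on the
3/4 training portion — no statistic of a test subject ever enters its own
model. 250 repeats × 4 folds = 1000 evaluations; MCE, sensitivity and
specificity are averaged over evaluations and selection frequency is the
fraction of evaluations whose signature contained the feature. A single
master seed (`numpy` SeedSequence spawning) drives subsampling, fold
splitting and inner CV, so a run is exactly reproducible, and ablation runs
under the same master seed share the subsample/fold schedule with the
unablated run, making paired comparisons meaningful. Sensitivity and
specificity are reported for a caller-chosen positive class (cancer in the
cancer-vs-inflammation contrast, inflammation vs controls).

**Stage-wise LOOCV.** Leave-one-out over a balanced set with fully nested
refitting; each held-out cancer subject's error is attributed to its TNM
stage. A stage with no subjects reports an undefined MCE, not zero.

**SUVmax augmentation.** SUVmax is appended as a 111th column and treated
exactly like an IR — autoscaled per training fold and exposed to selection —
so its usefulness is measured by its selection frequency and the change in
MCE, mirroring the reported modest improvement.

## Diagnostics

ROC thresholds sit at midpoints between consecutive distinct marker values
plus ∓∞ sentinels; with the "lower ⇒ positive" orientation used for
glutamate, a value ≤ threshold is a cancer call. The empirical AUC is the
trapezoidal area, which equals the Mann–Whitney concordance probability with
ties counted ½ (asserted exactly in tests). The binormal closed form
Φ(|μ₁−μ₀|/√(σ₁²+σ₀²)) is provided separately; at the printed glutamate
moments it reproduces the published area 0.875, which is the package's
consistency check between the printed moments and the printed ROC. The
Youden cutoff maximizes sens + spec − 1 with ties broken toward the smaller
threshold. Predictive values can be derived either from integer confusion
counts or from printed rates at given class sizes; the rates path keeps
fractional expected cells (no rounding) so results are order-independent.

Combined rule: PET positive iff SUVmax ≥ 2.5; glutamate positive-for-cancer
iff value ≤ 0.31 (both boundaries inclusive for the cancer call, strict for
the benign complements). In the two discordant cells the reported call
follows the glutamate test by default (`discordant_call="pet"` flips this);
the discordant miss fraction is the share of cancer subjects in discordant
cells whose call is benign. Which arbiter the original discordance figure
assumed is not stated, so the convention is explicit and configurable.

## Numerical and testing choices

- Normalization requires a strictly positive total and returns vectors
  summing to 1 within 1e−9; all-zero inputs are errors, never NaNs.
- Cohort CSVs are written with 17-significant-digit floats and read with
  round-trip float parsing, so persistence is lossless.
- Property tests (hypothesis) are derandomized; simulation tests use fixed
  seeds chosen before inspection and compare against independent oracles
  (brute-force Mann–Whitney, threshold sweeps, OLS/direct-LDA at full rank,
  quadrature for the binormal form).
- Test problem sizes: the full-scale resampling-structure check runs the
  complete 250 × 4 schedule on the 269/108/347 cohort; behavioural and
  property checks use a reduced cohort (60/40/40, same marker moments and a
  proportionally scaled stage table) with 10–20 repeats, sizes chosen so the
  assertions have comfortable statistical margins.

## What the synthetic experiments show — and what they do not

Passing tests establish that the machinery is correct (no leakage, exact
resampling structure, oracle-matched statistics) and that its qualitative
behaviour matches the reported analysis: glutamate dominates selection, its
removal degrades classification, SUVmax adds a little, stage does not
modulate error under exchangeability. They do **not** reproduce the
real-data performance figures (MCE 12%/38%, sensitivity 89%, the
combined-rule rates): those depend on the unpublished per-subject joint
distribution of all 110 regions and SUVmax, which no generator constrained
only by printed group moments can recover. Quantities that *are* functions
of printed numbers alone — the binormal AUC 0.875 and the PPV/NPV arithmetic
(76/71% for PET-CT at sens/spec 96/23%; 92/69% at the glutamate cutoff's
85/81%) — are reproduced to printed precision (NPVs to within the 1–2
percentage points attributable to rounding in the source).

## Known limitations

- The 104 unpublished region bounds are placeholders; spectra integrated
  with this map are only meaningful for the pinned regions.
- Gamma marginals and the independence/copula options are conventions; real
  metabolite panels have richer covariance than any of them.
- The simplex truncation slightly depresses the inflammation glutamate mean
  at cohort level (see above).
- LOOCV with nested selection is O(n) model fits per call and is the slowest
  component; it is intended for balanced sets of a few hundred subjects.
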