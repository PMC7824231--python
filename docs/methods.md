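# Methods

## Outcome: delta residuals

Beta values (methylation fractions, `β = M/(c + M + U)` with the Illumina
offset convention `c = 100` exposed as a parameter) are transformed to
M-values, `M = log2(β/(1−β))`, which are approximately Gaussian and suit
linear modelling. Betas are clipped to `[1e-6, 1 − 1e-6]` before the logit
so M stays finite; the inverse transform is exact to 1e-12 inside
`[0.01, 0.99]`.

At each age separately, M-values are regressed per CpG on an intercept,
five leukocyte fractions (granulocytes dropped — the six fractions sum to
one, so keeping all of them would be collinear with the intercept), and
three season dummies (winter reference). Because the design is shared by
all CpGs at a timepoint, the residuals are computed with a single
least-squares projection applied to the whole CpG × sample matrix; this is
exact, and residuals are orthogonal to every design column to 1e-8 of the
data scale. Covariate columns that are constant across samples are
absorbed by the intercept and dropped; any remaining rank deficiency is an
error that names the collinear columns. Subjects with missing covariates
are dropped from that timepoint (complete case). The analysis outcome is
the elementwise difference of residuals, age 10 minus birth, restricted to
CpGs and subjects present at both ages.

Probe QC follows array practice: a probe is kept when its detection
p-value beats 1e-16 in at least 95% of samples (boundary inclusive), when
no SNP sits within 10 bp with minor allele frequency above 7%, and when it
is autosomal.

## Feeding classification

The exclusivity cutoff is 13 weeks (≈ 3 months), boundary inclusive:

- **EBF** — only breastmilk for ≥ 13 weeks before formula or solids;
- **EFF** — never breastfed, formula only, solids not before 13 weeks;
- **Mixed** — any mixture of sources before 13 weeks.

A subject with no feeding information at all raises a classification error.

## Screening: training/testing robust regressions with surrogate variables

Surrogate variables capture systematic variation (batch, residual cell
heterogeneity) not in the model. After removing the fit on the feeding
indicator from every CpG, the surrogate variables are the leading right
singular vectors of the residual matrix. Their number is chosen by a
permutation scheme: entries of each CpG row are permuted independently 20
times, and leading components are kept while their singular values exceed
the 95th percentile of the **largest** permuted singular value. Comparing
against the largest permuted value, rather than component-by-component,
matters on residualized inputs: removing covariate fits leaves the delta
matrix mildly rank-deficient, so its whole spectrum sits a fraction of a
percent above an entrywise-permutation null and a componentwise rule then
admits dozens of spurious components; the max-based rule is immune to
that cascade and conservative. Under pure i.i.d. noise it keeps zero
components in ~95% of runs; on residualized null cohorts it typically
keeps at most one. Surrogate variables are estimated once on the full data and
reused across splits, which is more stable than re-estimating them inside
each split at n ≈ 200.

Each of 100 iterations splits the subjects into a 2/3 training and 1/3
testing set. Splits are stratified on the feeding indicator (proportional
allocation per level) so that a rare exposure group (EFF is ~9% of
subjects) is represented in both halves. Per CpG and per half, a robust
linear regression of the delta residual on the indicator plus surrogate
variables is fitted by iteratively reweighted least squares with Huber
weights (tuning constant 1.345, 95% Gaussian efficiency); the scale is
fixed at the MAD of the initial OLS residuals, and the feeding p-value
uses a t reference with n − p degrees of freedom on the weighted-LS
covariance. A CpG scores an iteration when p < 0.05 in **both** halves and
is selected when it scores ≥ 50% of iterations. Setting `robust=False`
replaces the IRLS fit with plain OLS and exact t-tests, which the test
suite uses for oracle comparisons. CpGs with zero variance within a split
are counted as non-significant for that iteration.

The defaults (100 iterations, 2/3 split, α = 0.05 in both halves, 50%
retention) follow the published defaults of the training/testing screening
approach this module reimplements; they are exposed in `ScreeningConfig`.

## Adjusted inference and FDR

Screened CpGs are re-tested by OLS with the full confounder set: sex, the
ten cell-fraction columns (five per age), six season dummies (three per
age), maternal age, maternal smoking, caesarean delivery, birthweight,
birth order (reference first-born), and SES (reference high). Cell and
season columns are re-included even though residualization already removed
them; they are near-orthogonal to the outcome and keeping them matches the
stated confounder list of the analysis this package operationalizes.
Benjamini–Hochberg adjustment is applied within each feeding mode's
screened set separately (three separate EWAS); the adjusted p-value is
never smaller than the raw one.

## Global shift statistics

Per subject: (a) the mean delta residual over all CpGs; (b) the percentage
of CpGs strictly below the population median of per-subject first
quartiles, and strictly above the median of third quartiles. Quartiles use
linear interpolation between order statistics (the mainstream numerical
default; documented so other implementations can match), and percentages
are on a 0–100 scale. Each per-subject statistic is regressed on EFF and
Mixed indicators (EBF reference) plus the same confounder design as the
EWAS. Normality of the three outcomes is reported (Shapiro–Wilk per
outcome plus Mardia-style multivariate skewness/kurtosis) but never gates
the pipeline.

A genuine global downward shift in the EFF group manifests as a negative
EFF coefficient on the mean outcome and a positive EFF coefficient on the
below-Q1 percentage — the sign pattern the acceptance checks assert.

## Stability between ages 10 and 18

Temporal stability of a CpG is assessed with a linear mixed model of the
M-value on an age indicator with a subject random intercept. For the
balanced paired design (every subject measured at both ages) the REML
solution is closed-form: the age effect is the mean within-subject
difference and the Wald test reduces to a paired t-test with n − 1 degrees
of freedom, which is what the implementation computes (verified against a
generic mixed-model fit in the test suite). A CpG is *dynamic* when
p < 0.1, deliberately liberal and unadjusted so that only clearly stable
CpGs are promoted as candidate biomarkers. Two timepoints cannot identify
random slopes, so the random-effects structure is intercept-only.

## Cohort representativeness

Binary variables: one-sample z-test of the sample proportion against the
cohort proportion, **without** continuity correction — this convention
reproduces the published two-decimal p-values recomputed in the acceptance
checks; the continuity-corrected variant is available via a flag.
Multi-category variables: Pearson goodness-of-fit chi-square against the
cohort proportions. Continuous variables: one-sample t-test from summary
statistics. The gene-location contingency tables (TSS vs not, gene body vs
not, multi-label probes counted in every group they match) are report-only:
a plain Pearson chi-square on the printed counts does not reproduce the
originally reported p-values for that table, so no acceptance value is
attached to it.

## Synthetic cohorts

The generator emulates the data-generating assumptions of the analysis,
on the M scale:

```
M_ij(t) = μ_i + u_ij + Σ_k γ_ik · cell_jk(t) + season_i(t)
          + d_i · 1[t = 10y]
          + effect · 1[t = 10y, i ∈ effect set of j's mode]
          + shift · 1[t = 10y, j is EFF]  + ε_ijt
```

- `μ_i`: bimodal baseline — betas drawn from a mirrored Beta(2, 8) mixture
  (hypo-/hyper-methylated probes), then logit-transformed, mirroring the
  U-shaped beta distribution of array data.
- `u_ij ~ N(0, 0.3)`: subject-level deviation carried across both ages, so
  a subject's baseline cancels in the delta.
- Cell fractions are Dirichlet: granulocyte-dominated at birth
  (α = 1.5, 3.5, 1, 1.5, 1.5, 11), more lymphocytes at age 10
  (α = 2.5, 5, 1.5, 2, 1.5, 7.5). Per-CpG cell coefficients γ_ik ~ N(0, 1)
  give realistic cell-composition structure.
- Seasons are uniform and independent at each age, with per-CpG season
  effects ~ N(0, 0.1) (winter zero).
- `d_i ~ N(0, 0.2)`: CpG-specific age drift shared by all subjects
  (removed by the intercept during residualization).
- `ε ~ N(0, noise_sd_m)` independently at each timepoint; default 0.5.

Defaults mirror the study conditions where they are known: 201 subjects;
feeding prevalences (0.229, 0.089, 0.682) for (EBF, EFF, Mixed); a global
EFF shift of −0.03 M-units; per-CpG feeding effects of 0.4 M-units
(typical of the reported per-CpG coefficient magnitudes) at 30 CpGs per
mode. The CpG count defaults to 10,000 — a desk-scale stand-in for a
filtered array of ~292k probes — and the calibration suites run at 2,000
CpGs × 200 subjects × 20 seeds, sizes at which every calibration property
is comfortably measurable. Feeding durations are drawn consistently with
each subject's mode and round-trip through the classifier exactly.

What the generator does **not** emulate: raw IDAT intensities,
probe cross-hybridization, batch/chip effects (assumed removed upstream),
spatial correlation along the genome, and non-Gaussian heavy-tailed probe
noise. Passing calibration tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real arrays.

## Numerical conventions and edge cases

- Detection-rate boundary "at least 95%" is inclusive; 13-week feeding
  exclusivity is inclusive.
- Beta clipping 1e-6; quartiles by linear interpolation; strict
  inequalities for below/above counts; an all-equal delta matrix yields
  zero percentages with a warning.
- Zero-variance CpGs never become significant (p set to 1).
- BH adjustment delegates to statsmodels' step-up implementation; the test
  suite checks it against a literal independent reimplementation.
- All randomness flows through `numpy.random.default_rng` seeded from the
  relevant config; identical seeds reproduce outputs bit-for-bit.

## Known limitations

- Robust-regression p-values use a pragmatic weighted-LS covariance with a
  t reference rather than a fully efficient robust covariance; exactness
  is only claimed (and tested) for the OLS path.
- Screening then re-testing the selected CpGs on the same data inflates
  the apparent FDR of the adjusted stage; the package mirrors that
  two-stage design rather than correcting it, and the end-to-end error
  control claimed is the screening stage's, measured by simulation.
- With only two timepoints the stability model cannot separate measurement
  error from true short-term fluctuation.
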