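# deltamethyl

Longitudinal epigenome-wide association analysis of infant feeding mode and
the **change** in DNA methylation from birth to mid-childhood, with a
synthetic-cohort generator for calibration and ground-truth testing.

## The problem

Most association studies of infant feeding (breastfeeding vs formula) and
DNA methylation (DNAm) measure methylation at a single childhood timepoint,
so a difference observed at, say, age 10 cannot be separated from a
difference that already existed at birth. This package implements the
longitudinal alternative: analyse the *delta residual*

```
ΔDNAm_ij = residDNAm_ij(age 10) − residDNAm_ij(birth)
```

where `residDNAm_ij` is the residual of the M-value (logit2 of the beta
value, `M = log2(β / (1 − β))`) of CpG *i* in subject *j* after regressing
out estimated leukocyte cell-type proportions (CD8T, CD4T, NK, B cells,
monocytes, granulocytes) and season of blood collection at each age
separately. Feeding exposure is classified with a 13-week exclusivity
cutoff into exclusive breastfeeding (EBF), exclusive formula feeding (EFF),
and mixed feeding.

The pipeline then:

1. **Screens** all CpGs per feeding mode by repeated training/testing
   splits of robust (Huber) linear regressions of `ΔDNAm(CpG_i) = α + β₁ ·
   feeding + surrogate variables`, keeping a CpG only if the feeding term
   replicates (p < 0.05) in both halves in at least half of 100 random
   splits.
2. **Tests** the screened CpGs in confounder-adjusted OLS models (sex, cell
   composition and season at both ages, maternal age, maternal smoking,
   delivery mode, birthweight, birth order, socioeconomic status), with
   Benjamini–Hochberg FDR control within each mode.
3. **Quantifies the epigenome-wide shift** with per-subject summaries: the
   mean of ΔDNAm over all CpGs, and the percentage of CpGs below the
   population-median first quartile (pronounced declines) or above the
   median third quartile (pronounced rises), each regressed on feeding
   mode (EBF reference) with the same confounders.
4. **Reports** cohort representativeness (one-sample proportion, GOF
   chi-square and one-sample t tests), gene-location tables, per-CpG
   temporal stability between ages 10 and 18 (random-intercept mixed
   model, dynamic iff p < 0.1), and per-feeding-group outcome regressions.

## Worked example

```python
import deltamethyl as dm

cfg = dm.SimConfig(n_subjects=200, n_cpgs=2000, n_effect_cpgs_per_mode=50,
                   effect_size_m=1.0, noise_sd_m=0.5, seed=1)
mb, m10, sheet, truth = dm.simulate_cohort(cfg)
delta = dm.delta_pipeline(mb, m10, sheet)

ind = (sheet["feeding_mode"] == "EFF").to_numpy().astype(int)
svs = dm.estimate_surrogate_variables(delta, ind, seed=1)
res = dm.tt_screen(delta, ind, svs, dm.ScreeningConfig(seed=1))
hits = set(res.selected_cpgs) & set(truth.effect_cpg_ids["EFF"])
print(f"recovered {len(hits)}/50 injected CpGs")

shift = dm.run_global_shift(delta, sheet)
print(shift.mean_delta.round(4))
```

prints

```
recovered 50/50 injected CpGs
        coeff      se       p
EFF   -0.0288  0.0045  0.0000
Mixed  0.0007  0.0032  0.8198
```

All 50 CpGs carrying the injected 1.0 M-unit birth-to-age-10 effect for
exclusively formula-fed subjects pass the training/testing screen. The
global regression estimates the mean ΔDNAm difference between EFF and EBF
subjects: the generator's default −0.03 M-unit global EFF shift is
recovered as −0.0288, while the mixed-feeding coefficient is
indistinguishable from zero.

The same steps are available from a shell:

```bash
deltamethyl simulate --out cohort/ --seed 1
deltamethyl preprocess --birth cohort/beta_birth.tsv --age10 cohort/beta_age10.tsv \
    --sheet cohort/sample_sheet.csv --out work/
deltamethyl screen --delta work/delta.tsv --sheet cohort/sample_sheet.csv \
    --mode EFF --seed 1 --out work/screen_EFF.tsv
deltamethyl ewas --delta work/delta.tsv --screen EFF work/screen_EFF.tsv \
    --sheet cohort/sample_sheet.csv --out work/ewas.tsv
deltamethyl global --delta work/delta.tsv --sheet cohort/sample_sheet.csv \
    --out work/global.tsv
```

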