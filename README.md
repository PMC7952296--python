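# epimatch

Epitope-load HLA matching for kidney transplantation: a PIRCHE-II-style
scoring engine, haplotype-frequency imputation from split-level typings,
log-adjustment of scores onto the 0–6 antigen-mismatch scale, and
multivariable Cox survival models that compare the adjusted epitope score
against the classic HLA A+B+DRB1 mismatch count. The package is aimed at
transplant immunogenetics and registry-analysis groups who want a tested,
end-to-end reference implementation of this comparison that runs without
access to any registry data: a built-in generator simulates transplant
cohorts with the statistical structure the analysis assumes.

## The science in brief

**Epitope-load score.** For a donor/recipient pair of two-field HLA
genotypes, the score counts the donor-derived HLA peptides a recipient's
CD4+ T cells could indirectly recognise: every 15-mer of the donor's
HLA-A/B/DRB1 proteins that (i) does not occur in the recipient's own
HLA protein repertoire and (ii) is predicted to be presented by a
recipient HLA-DRB1 molecule. Presented peptides are deduplicated by their
9-mer binding core, once per presenting DRB1 protein. The presentation
predictor is pluggable; a deterministic position-weight-matrix predictor
is bundled.

**Imputation.** Deceased-donor allocation typing is split-level, not
molecular. Each split typing is expanded into all compatible A~B~DRB1
haplotype pairs, weighted by Hardy–Weinberg pairing of population
haplotype frequencies (f₁f₂, doubled for heterozygous pairs) and
renormalised; the frequency-weighted mean score and its SD propagate the
genotype uncertainty.

**Scale adjustment.** Raw scores (0 to a few hundred, log-shaped effect)
are mapped onto the mismatch scale by

    adjusted_i = ln(raw_i + 1) · 6 / max_j ln(raw_j + 1)

so 0 ↦ 0 and the cohort maximum ↦ 6, making per-unit hazard ratios
directly comparable with the per-mismatch HR.

**Survival comparison.** Three country-stratified Cox models of 5-year
death-censored graft survival (mismatches only, adjusted score only,
both), with registry-style confounders and explicit "unknown" levels;
cross-categorised subgroup fits (effect of one exposure within categories
of the other), AIC ranking, and AUC of the linear predictor.

## Worked example

```python
import epimatch as em

cfg = em.GeneratorConfig(seed=1)                 # n_patients=20,000 default
ref = em.synthesize_reference_data(cfg)
cohort = em.simulate_cohort(cfg, ref)
data = cohort.data

rho, p = em.spearman_correlation(data.hla_mm, data.pirche_raw)
fits = {s: em.fit_cox(data, exposure_spec=s)
        for s in ("hla_only", "pirche_only", "both")}
print(em.compare_models(fits))
print(fits["both"].summary())
```

With seed 1 this prints (abbreviated): raw scores span 0–129 with
Spearman ρ = 0.58 against the mismatch count; the single-exposure models
give HR 1.165/mismatch (z = 12.9) and HR 1.193/adjusted-score unit
(z = 11.9), while the joint model attenuates both to 1.101 and 1.117 —
the expected collinearity pattern, since both exposures measure the same
donor–recipient incompatibility. The joint model wins on AIC (71,469 vs
71,506/71,507) and its linear predictor has AUC 0.62 for graft loss by 60
months. The true simulated effects behind these numbers are
HR 1.102/adjusted-score unit and 1.095/mismatch, both inside the joint
model's 95% CIs.

The same pipeline is scriptable from a shell:

```bash
epimatch simulate --n 20000 --seed 1 --outdir run/
epimatch impute --cohort run/cohort.csv --haplotypes run/reference/haplotypes.csv \
    --fasta run/reference/alleles.fasta --split-map run/reference/split_map.csv \
    --pwm run/reference/pwm.yaml --out run/imputed.csv
epimatch adjust --cohort run/imputed.csv --out run/adjusted.csv --context-out run/ctx.yaml
epimatch fit --cohort run/adjusted.csv --model both --subgroups coarse2x2
```

## Layout

- `epimatch.hla` — allele library, split typings, genotypes, mismatch counting
- `epimatch.epitopes` — 15-mer enumeration, self-peptidome, PWM predictor, scoring
- `epimatch.imputation` — haplotype tables, genotype completions, weighted score moments
- `epimatch.transform` — 0–6 log adjustment, category schemes, rank correlation
- `epimatch.survival` — `GraftSurvivalModel` / `GraftSurvivalResults`, subgroup and AIC/AUC tools
- `epimatch.cohort` — synthetic reference data and cohort generator
- `epimatch.cli` — the `epimatch` command

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
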