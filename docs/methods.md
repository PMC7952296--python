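# Methods

This note documents the models and procedures implemented in `epimatch`,
the assumptions they rest on, the parameters that matter, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Epitope-load scoring

For a donor genotype D and recipient genotype R (two-field alleles at
HLA-A, -B, -DRB1), the raw score is

1. enumerate all 15-mers (stride 1) of the distinct donor allele proteins
   at the donor loci (default A, B, DRB1);
2. discard every 15-mer that occurs in the recipient self-peptidome — the
   union of 15-mers of the recipient's proteins at the self loci (default
   A, B, DRB1; HLA-C/DQB1 can be added via `self_loci`). Subtraction uses
   exact 15-mer identity, not core identity;
3. query the presentation predictor for every surviving 15-mer against
   each distinct recipient DRB1 allele;
4. count distinct (9-mer core, presenting DRB1 allele) pairs.

Deduplication is per presenter: the same core presented by two different
DRB1 proteins counts twice, identical cores from different donor 15-mers
under one presenter count once. The quoted counting rule ("once per
presented protein") supports this reading; because the alternative
(a global core set) is defensible, it remains a one-argument switch
(`dedup_scope="global"`).

Sequences are assumed to be supplied already restricted to the
exon-2–5-encoded region; the package does not compute exonic coordinates.

### Presentation predictor

The predictor is a contract: deterministic map from (15-mer, DRB1 allele)
to (presented?, 9-mer core, affinity). The bundled `PwmPredictor` scores
each of the seven 9-mer windows by a per-allele 9×20 position-weight
matrix, takes the maximal window as the core (leftmost on ties, so runs
are bit-reproducible), and presents iff the maximum reaches a global
threshold. It is a deliberately simple, fully transparent model of MHC
class II binding preferences; trained neural predictors can be plugged in
behind the same contract without touching the scoring chain. Scores with
the PWM predictor should be read as method-internal quantities, not as
immunological affinities.

## Imputation from split typings

A split typing constrains but does not determine the genotype. The
completion distribution is: all unordered haplotype pairs (h₁, h₂) from
the frequency table whose per-locus split projection matches the typing,
with prior weight f(h₁)f(h₂), doubled when h₁ ≠ h₂ (Hardy–Weinberg random
pairing), renormalised over the compatible set — i.e. the conditional
genotype distribution given the observed typing under HWE. Haplotype
pairs that collapse to the same genotype are merged. Donor and recipient
completions are treated as independent (no linkage between two
individuals), and the pair-score distribution is their product. The
reported point estimate is the weighted **mean** (left unrounded); the
weighted SD quantifies the typing-resolution uncertainty. Assumptions:
the frequency table matches the population the patients come from, and
HWE holds; both fail gracefully (the distribution is still proper) but
bias the moments when violated.

Mean and SD use the central-moment form, which is stable when the score
barely varies across completions.

## Mismatch counting

Donor-antigen-not-in-recipient at split level: per locus, the number of
distinct donor split antigens absent from the recipient's two antigens,
at most 2 per locus, 0–6 in total. A homozygous donor antigen missing
from the recipient counts once. Split labels are opaque strings; no
broad/split hierarchy is resolved. One caveat discovered while
property-testing: "giving the recipient a donor antigen" is only
guaranteed not to increase the count when the replaced recipient antigen
is one the donor does not carry — replacing a matched antigen can
unmatch it.

## Scale adjustment

adjusted = ln(raw+1) · 6 / max ln(raw+1), the maximum taken over the
cohort being analysed. The fitted maximum is stored in an
`AdjustmentContext` so new patients (e.g. at allocation time) get the
identical mapping rather than a refit. The transform is strictly
monotone, maps 0 to 0 and the cohort maximum to 6, and is undefined
(an error) when every raw score is zero. Raw-score category boundaries
(0–1, 2–12, 13–25, 26–43, 44–68, 69–102, >102; coarse 0–12/>12 and
0–3/4–6 mismatch groupings) are fixed constants with inclusive upper
bounds, applied to raw scores by default; non-integer imputed means use
the same value ≤ upper-bound rule. A helper derives "similarly sized"
boundaries by rank for synthetic cohorts.

## Survival models

Cox proportional hazards on death-censored graft survival, horizon 60
months by default (administrative censoring: times clipped, later events
recoded as censored). Death with a functioning graft is treated as
non-informative censoring; competing risks are out of scope. Baseline
hazards are stratified by country; strata without events are dropped with
a warning. Continuous confounders (recipient/donor age, cold ischemia
time, dialysis months) enter linearly; categorical confounders enter as
dummies with missing values recoded to an explicit "unknown" level.
Covariates constant in the analysed (sub)cohort are pruned automatically.
The partial likelihood is maximised by lifelines' `CoxPHFitter` with
Efron tie handling (the only tie method that optimiser implements; a
Breslow switch is therefore not offered). No multiplicity correction is
applied to subgroup p-values; they are nominal.

Model comparison uses the partial-likelihood AIC. Discrimination is the
AUC of the fitted linear predictor against "graft lost by the horizon",
excluding subjects censored before the horizon without an event, whose
status is unknown.

Cross-categorised subgroup analysis fits the both-exposure model inside
each category of the other exposure (7 mismatch strata, 7 raw-score
strata, or the 2×2 coarse grouping); where the stratifying exposure is
constant within a stratum it is pruned, so the fit degenerates to the
single-exposure model there. Subgroups under a configurable minimum
number of events are flagged, not fitted.

## Synthetic cohorts

The generator emulates the statistical skeleton a registry analysis
needs, not demographic realism (no era trends or country mix; margins are
simple fixed laws).

Reference data: per locus one ancestral toy protein (default length 120)
diverges into 4 split antigens at 0.25 substitutions/site, each split
into 2 alleles at 0.04 — between-split divergence drives the non-self
peptide load, so these two rates set the raw-score scale. Defaults were
chosen so scores span roughly 0–130 with a score/mismatch Spearman ρ
around 0.55–0.6, mirroring the scale relationships of registry-style
cohorts (score range an order of magnitude above the 0–6 mismatch count,
strong but imperfect rank correlation). 20 A~B~DRB1 haplotypes get
Dirichlet(1) frequencies; PWMs are standard-normal with the presentation
threshold set at the pooled best-window quantile giving a 35% presented
fraction.

Cohorts: donor and recipient genotypes are independent HWE haplotype
pairs; typings are their split projections; mismatch counts and TRUE
scores are computed from the true genotypes (no imputation noise), while
the emitted split typings let the imputation module's error be studied
against this ground truth. Graft-loss times are exponential proportional
hazards with linear predictor

βP·adjusted + βH·mismatches + confounder effects,

βP = ln(1.102), βH = ln(1.095) by default; an interaction switch gates
the epitope term to pairs above 3 mismatches. The baseline is exponential
with rate 0.0021 per month (≈12% 5-year loss at lp = 0); a Weibull shape
parameter (cumulative hazard rate·t^k, default k = 1) is available for
non-constant baselines. Censoring is independent exponential at 0.002 per
month plus a 120-month administrative cap. Confounders are
independent of the exposures by default (a `confounded` toggle correlates
donor age with mismatch count for sensitivity tests); "unknown" levels
appear at registry-like rates (PRA 23%, dialysis 22%, treatment 6%). The
default cohort size of 20,000 keeps a full simulate-plus-fit cycle at a
few seconds while leaving per-unit HR standard errors small (~0.02).
Everything derives from the config seed; identical configs reproduce
identical cohorts.

What passing tests on these cohorts do **not** show: performance on real
registry data, with linkage disequilibrium across populations, typing-era
artefacts, informative censoring, or non-proportional hazards — none of
which the generator emulates.

## Parameter recovery and attenuation checks

The recovery suite verifies, at n = 20,000 over 50 replicates, that the
single-exposure Cox fit covers its true HR in ≥90% of replicates. Each
exposure is assessed in a simulation where it carries the sole exposure
effect: because score and mismatch count are positively correlated by
construction, a single-exposure fit with both effects active is
misspecified (omitted-variable bias) and *should not* attain nominal
coverage — that inflation is exactly the single-versus-joint attenuation
the suite checks separately with both effects active, where the joint
model's CIs do cover both true HRs.

## Numerical choices and degenerate inputs

- Core-window ties: leftmost window wins (strict `>` comparison).
- Weighted SDs: central-moment accumulation; negative variance from
  round-off clamps to zero.
- All-zero score cohorts: adjustment raises; the generator emits
  all-zero adjusted scores in the degenerate zero-divergence case.
- Unresolvable typings (no compatible haplotype pair): hard error naming
  the uncovered loci in `enumerate_completions`; flagged-but-kept rows in
  batch cohort scoring.
- Rank correlation on a constant vector: error, not NaN.
- Completion caches and predictor memoisation are safe because every
  scored quantity is a deterministic function of its inputs.

## Known limitations

- The PWM predictor is a structural stand-in; absolute score magnitudes
  are not comparable to scores from trained class II predictors.
- Only DRB1 presents; self loci beyond A/B/DRB1 are configurable but
  untrained toy sequences make C/DQB1 additions cosmetic in synthetic
  data.
- Single-population haplotype tables only; no admixture mixtures or
  EM frequency estimation.
- The Cox stage offers no time-varying effects, frailty, or competing
  risks.
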