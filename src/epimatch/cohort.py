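"""Synthetic transplant cohorts with the structure the analysis assumes.

Registry-scale transplant data is not freely redistributable, so this
module builds everything the pipeline needs from scratch: a toy allele
library whose sequence divergence drives realistic epitope-load scales, a
haplotype-frequency table, a PWM presentation predictor, and per-patient
transplant records with correlated epitope score and mismatch count,
registry-style confounders (including explicit "unknown" levels), and
death-censored graft-loss times drawn from an exponential
proportional-hazards model.

The generator computes TRUE scores from true genotypes (no imputation
noise) while also emitting split typings, so imputation error can be
studied against ground truth. Every random draw flows from the config
seed; identical configs reproduce identical cohorts byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .epitopes import AA20, GenotypePairScorer, PwmPredictor, PEPTIDE_LENGTH
from .hla import LOCI, AlleleLibrary, AlleleRecord, Genotype, SplitTyping, count_hla_mismatches
from .imputation import Haplotype, HaplotypeTable
from .transform import AdjustmentContext, adjust_scores

_SPLIT_PREFIX = {"A": "A", "B": "B", "DRB1": "DR"}


class GeneratorError(ValueError):
    """Degenerate generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    The default true per-unit log-hazards are ln(1.102) per adjusted-score
    unit and ln(1.095) per mismatch; the default cohort size of 20,000 is
    the desk-scale stand-in for a registry-sized collective.
    """

    seed: int
    n_patients: int = 20_000
    # reference-data shape
    n_haplotypes: int = 20
    dirichlet_concentration: float = 1.0
    n_splits_per_locus: int = 4
    alleles_per_split: int = 2
    protein_length: int = 120
    split_divergence: float = 0.25
    allele_divergence: float = 0.04
    alphabet: str = AA20
    presented_fraction: float = 0.35
    # true effects
    beta_pirche: float = math.log(1.102)
    beta_hla: float = math.log(1.095)
    interaction: bool = False
    interaction_mm_threshold: int = 3
    confounded: bool = False
    effect_recipient_age: float = 0.010
    effect_donor_age: float = 0.012
    effect_cit: float = 0.010
    effect_pra_pos: float = 0.30
    effect_marginal: float = 0.20
    # incomplete-observation rates
    pra_unknown_rate: float = 0.23
    pra_positive_fraction: float = 0.166
    dialysis_unknown_rate: float = 0.22
    treatment_unknown_rate: float = 0.06
    # survival process (per-month rates); weibull_shape=1 is the
    # exponential baseline, shape k gives cumulative hazard rate * t^k
    baseline_hazard: float = 0.0021
    weibull_shape: float = 1.0
    censor_rate: float = 0.0020
    followup_cap: float = 120.0
    n_countries: int = 5

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise GeneratorError("a seed is mandatory and must be an integer")
        if self.n_patients < 1:
            raise GeneratorError("n_patients must be >= 1")
        if self.n_splits_per_locus < 1 or self.alleles_per_split < 1:
            raise GeneratorError("need at least one split and one allele per split")
        if self.protein_length < PEPTIDE_LENGTH:
            raise GeneratorError(f"protein_length must be >= {PEPTIDE_LENGTH}")
        for name in ("baseline_hazard", "censor_rate", "split_divergence", "allele_divergence"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be non-negative")
        if self.n_haplotypes < 1:
            raise GeneratorError("need at least one haplotype")
        if self.weibull_shape <= 0:
            raise GeneratorError("weibull_shape must be positive")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class ReferenceData:
    """Allele library, split map, haplotype table and predictor, as one unit."""

    library: AlleleLibrary
    split_map: pd.DataFrame
    haplotypes: HaplotypeTable
    predictor: PwmPredictor
    _scorer: GenotypePairScorer | None = field(default=None, repr=False)

    @property
    def pair_scorer(self) -> GenotypePairScorer:
        """Shared memoised scorer (caches persist across cohorts)."""
        if self._scorer is None:
            self._scorer = GenotypePairScorer(self.library, self.predictor)
        return self._scorer

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "alleles.fasta", "w") as fh:
            for rec in self.library:
                fh.write(f">{rec.name} split={rec.split}\n{rec.protein}\n")
        self.split_map.to_csv(outdir / "split_map.csv", index=False)
        self.haplotypes.to_frame().to_csv(outdir / "haplotypes.csv", index=False)
        self.predictor.to_yaml(outdir / "pwm.yaml")


def _mutate(seq: np.ndarray, rate: float, alphabet: str, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute each site with probability `rate` (to a different letter)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def synthesize_reference_data(config: GeneratorConfig) -> ReferenceData:
    """Generate the allele library, split map, haplotype table and PWMs.

    Alleles at each locus descend from one ancestral toy protein: split
    antigens diverge at ``split_divergence`` substitutions per site and
    alleles within a split at ``allele_divergence``, so the divergence
    rates control how many non-self peptides a mismatched genotype
    carries, hence the raw score scale.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    alphabet = config.alphabet
    records: list[AlleleRecord] = []
    for locus in LOCI:
        ancestral = np.array(list(alphabet))[
            rng.integers(len(alphabet), size=config.protein_length)
        ]
        for s in range(config.n_splits_per_locus):
            split_anc = _mutate(ancestral, config.split_divergence, alphabet, rng)
            split_label = f"{_SPLIT_PREFIX[locus]}{s + 1}"
            for j in range(config.alleles_per_split):
                allele_seq = _mutate(split_anc, config.allele_divergence, alphabet, rng)
                records.append(
                    AlleleRecord(
                        locus=locus,
                        name=f"{locus}*{s + 1:02d}:{j + 1:02d}",
                        split=split_label,
                        protein="".join(allele_seq),
                    )
                )
    library = AlleleLibrary(records)
    split_map = pd.DataFrame(
        [(r.name, r.split) for r in library], columns=["allele", "split"]
    )

    # haplotypes: a random subset of the allele product, Dirichlet frequencies
    names = {locus: [r.name for r in library.alleles_at(locus)] for locus in LOCI}
    n_combos = int(np.prod([len(names[loc]) for loc in LOCI]))
    n_hap = min(config.n_haplotypes, n_combos)
    chosen = rng.choice(n_combos, size=n_hap, replace=False)
    freqs = rng.dirichlet(np.full(n_hap, config.dirichlet_concentration))
    freqs = np.maximum(freqs, 1e-9)
    haps = []
    n_b, n_dr = len(names["B"]), len(names["DRB1"])
    for idx, f in zip(chosen, freqs):
        ia, rem = divmod(int(idx), n_b * n_dr)
        ib, idr = divmod(rem, n_dr)
        haps.append(
            Haplotype(a=names["A"][ia], b=names["B"][ib], drb1=names["DRB1"][idr], freq=float(f))
        )
    table = HaplotypeTable(haps)

    # PWMs per DRB1 allele; threshold set as a pooled best-window quantile
    matrices = {
        name: rng.normal(0.0, 1.0, size=(9, len(alphabet))) for name in names["DRB1"]
    }
    probe = PwmPredictor(matrices, threshold=-np.inf, alphabet=alphabet)
    peptides = set()
    for rec in library:
        for i in range(len(rec.protein) - PEPTIDE_LENGTH + 1):
            peptides.add(rec.protein[i : i + PEPTIDE_LENGTH])
    best_scores = [
        probe.predict(pep, library.get(drb1)).affinity_score
        for pep in sorted(peptides)
        for drb1 in names["DRB1"]
    ]
    threshold = float(np.quantile(best_scores, 1.0 - config.presented_fraction))
    predictor = PwmPredictor(matrices, threshold=threshold, alphabet=alphabet)
    return ReferenceData(
        library=library, split_map=split_map, haplotypes=table, predictor=predictor
    )


@dataclass
class SyntheticCohort:
    """Simulated cohort plus its ground truth and generating objects."""

    data: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GeneratorConfig
    reference: ReferenceData
    adjustment: AdjustmentContext | None


def _typing_fields(t: SplitTyping) -> tuple[str, ...]:
    return (*t.a, *t.b, *t.drb1)


def simulate_cohort(
    config: GeneratorConfig, reference: ReferenceData | None = None
) -> SyntheticCohort:
    """Simulate one transplant cohort under the configured conditions.

    Donor and recipient genotypes are Hardy-Weinberg haplotype pairs;
    split typings, mismatch counts and true epitope scores follow from
    the reference data; graft-loss times come from an exponential (or
    Weibull, via ``weibull_shape``) proportional-hazards model with
    linear predictor
    ``beta_pirche * adjusted + beta_hla * mismatches + confounders``
    (epitope term gated above the mismatch threshold when `interaction`
    is set), with independent exponential censoring and an administrative
    follow-up cap. Death with function is part of the censoring process.
    """
    if reference is None:
        reference = synthesize_reference_data(config)
    rng = np.random.default_rng([int(config.seed), 1])
    n = config.n_patients

    freqs = np.array([h.freq for h in reference.haplotypes])
    freqs = freqs / freqs.sum()
    n_hap = len(freqs)
    d_idx = rng.choice(n_hap, size=(n, 2), p=freqs)
    r_idx = rng.choice(n_hap, size=(n, 2), p=freqs)

    haps = reference.haplotypes.haplotypes
    geno_cache: dict[tuple[int, int], Genotype] = {}
    typing_cache: dict[Genotype, SplitTyping] = {}

    def genotype_of(i: int, j: int) -> Genotype:
        key = (i, j) if i <= j else (j, i)
        g = geno_cache.get(key)
        if g is None:
            h1, h2 = haps[key[0]], haps[key[1]]
            g = Genotype.from_pairs({loc: (h1.allele(loc), h2.allele(loc)) for loc in LOCI})
            geno_cache[key] = g
        return g

    def typing_of(g: Genotype) -> SplitTyping:
        t = typing_cache.get(g)
        if t is None:
            t = g.split_typing(reference.library)
            typing_cache[g] = t
        return t

    scorer = reference.pair_scorer
    mm_cache: dict[tuple[Genotype, Genotype], int] = {}
    raw = np.empty(n)
    mm = np.empty(n, dtype=int)
    d_fields, r_fields, d_names, r_names = [], [], [], []
    for k in range(n):
        dg = genotype_of(int(d_idx[k, 0]), int(d_idx[k, 1]))
        rg = genotype_of(int(r_idx[k, 0]), int(r_idx[k, 1]))
        dt, rt = typing_of(dg), typing_of(rg)
        key = (dg, rg)
        m = mm_cache.get(key)
        if m is None:
            m = count_hla_mismatches(dt, rt).total
            mm_cache[key] = m
        mm[k] = m
        raw[k] = scorer(dg, rg)
        d_fields.append(_typing_fields(dt))
        r_fields.append(_typing_fields(rt))
        d_names.append("/".join(dg.unique_allele_names()))
        r_names.append("/".join(rg.unique_allele_names()))

    if raw.max() > 0:
        adj, ctx = adjust_scores(raw)
    else:  # fully homogeneous population: no epitope signal to scale
        adj, ctx = np.zeros(n), None

    # confounders (independent of the exposures unless `confounded` is set)
    recipient_age = np.clip(rng.normal(49.0, 15.0, n), 18.0, 80.0)
    donor_age = np.clip(rng.normal(47.0, 17.0, n), 5.0, 85.0)
    if config.confounded:
        donor_age = np.clip(donor_age + 3.0 * (mm - mm.mean()), 5.0, 90.0)
    recipient_sex = rng.choice(["male", "female"], size=n, p=[0.62, 0.38])
    donor_sex = rng.choice(["male", "female"], size=n, p=[0.565, 0.435])
    cit_hours = np.clip(rng.normal(17.0, 7.0, n), 1.0, 48.0)

    u = rng.random(n)
    dialysis_status = np.where(
        u < 0.02, "none", np.where(u < 0.02 + config.dialysis_unknown_rate, "unknown", "ongoing")
    )
    dialysis_months = np.where(
        dialysis_status == "ongoing", np.clip(rng.normal(45.0, 38.0, n), 0.0, 300.0), 0.0
    )
    disease = rng.choice(
        ["glomerulonephritis", "diabetes", "polycystic", "hypertension", "other", "unknown"],
        size=n,
        p=[0.25, 0.15, 0.10, 0.10, 0.30, 0.10],
    )
    u = rng.random(n)
    pra = np.where(
        u < config.pra_unknown_rate,
        "unknown",
        np.where(
            u < config.pra_unknown_rate + (1 - config.pra_unknown_rate) * config.pra_positive_fraction,
            "pos",
            "0",
        ),
    )
    marginal_donor = rng.choice(["no", "yes"], size=n, p=[0.85, 0.15])
    tu = config.treatment_unknown_rate
    induction = rng.choice(
        ["none", "il2ra", "atg", "other", "unknown"],
        size=n,
        p=[0.55 * (1 - tu) / 0.94, 0.24 * (1 - tu) / 0.94, 0.10 * (1 - tu) / 0.94,
           0.05 * (1 - tu) / 0.94, tu],
    )
    immunosuppression = rng.choice(
        ["tac_mpa", "csa_mpa", "other", "unknown"],
        size=n,
        p=[0.32 * (1 - tu) / 0.94, 0.23 * (1 - tu) / 0.94, 0.39 * (1 - tu) / 0.94, tu],
    )
    era = rng.choice(
        ["1990-1996", "1997-2003", "2004-2010", "2011-2016"],
        size=n,
        p=[0.13, 0.29, 0.30, 0.28],
    )
    country_probs = np.arange(1, config.n_countries + 1, dtype=float)
    country_probs /= country_probs.sum()
    country = rng.choice(
        [f"C{k + 1}" for k in range(config.n_countries)], size=n, p=country_probs
    )

    pirche_term = adj * (mm > config.interaction_mm_threshold) if config.interaction else adj
    lp = (
        config.beta_pirche * pirche_term
        + config.beta_hla * mm
        + config.effect_recipient_age * (recipient_age - 49.0)
        + config.effect_donor_age * (donor_age - 47.0)
        + config.effect_cit * (cit_hours - 17.0)
        + config.effect_pra_pos * (pra == "pos")
        + config.effect_marginal * (marginal_donor == "yes")
    )

    # Weibull PH inversion: S(t) = exp(-rate * t^k * e^lp); k = 1 is exponential
    e = rng.exponential(1.0, size=n)
    t_event = (e / (config.baseline_hazard * np.exp(lp))) ** (1.0 / config.weibull_shape)
    t_censor = (
        rng.exponential(1.0 / config.censor_rate, size=n)
        if config.censor_rate > 0
        else np.full(n, np.inf)
    )
    time = np.maximum(np.minimum.reduce([t_event, t_censor, np.full(n, config.followup_cap)]), 1e-6)
    event = ((t_event <= t_censor) & (t_event <= config.followup_cap)).astype(int)

    typing_cols = pd.DataFrame(
        [df + rf for df, rf in zip(d_fields, r_fields)],
        columns=[
            "donor_a1", "donor_a2", "donor_b1", "donor_b2", "donor_dr1", "donor_dr2",
            "recipient_a1", "recipient_a2", "recipient_b1", "recipient_b2",
            "recipient_dr1", "recipient_dr2",
        ],
    )
    data = pd.concat(
        [
            typing_cols,
            pd.DataFrame(
                {
                    "hla_mm": mm,
                    "pirche_raw": raw,
                    "pirche_adj": adj,
                    "recipient_age": recipient_age,
                    "donor_age": donor_age,
                    "recipient_sex": recipient_sex,
                    "donor_sex": donor_sex,
                    "cit_hours": cit_hours,
                    "dialysis_status": dialysis_status,
                    "dialysis_months": dialysis_months,
                    "disease": disease,
                    "pra": pra,
                    "marginal_donor": marginal_donor,
                    "induction": induction,
                    "immunosuppression": immunosuppression,
                    "era": era,
                    "country": country,
                    "time": time,
                    "event": event,
                }
            ),
        ],
        axis=1,
    )
    ground_truth = pd.DataFrame(
        {
            "donor_alleles": d_names,
            "recipient_alleles": r_names,
            "linear_predictor": lp,
            "true_event_time": t_event,
        }
    )
    ground_truth.attrs["beta_pirche"] = config.beta_pirche
    ground_truth.attrs["beta_hla"] = config.beta_hla
    return SyntheticCohort(
        data=data, ground_truth=ground_truth, config=config, reference=reference, adjustment=ctx
    )
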