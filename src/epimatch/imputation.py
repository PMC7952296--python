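"""Genotype imputation from split typings via haplotype frequencies.

A split-level typing is compatible with many two-field genotypes. This
module enumerates every A~B~DRB1 haplotype pair whose split projection
matches the observed typing, weights pairs by Hardy-Weinberg random
pairing (f1*f2, doubled for heterozygous pairs), renormalises over the
compatible set, and propagates the resulting genotype distribution
through an epitope scorer to a frequency-weighted mean score and its
standard deviation. The SD quantifies how precisely the epitope load is
determined by split-level typing alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .hla import (
    LOCI,
    AlleleLibrary,
    Genotype,
    HlaError,
    SplitTyping,
    count_hla_mismatches,
    parse_split_typing,
)

#: column names of the haplotype-frequency CSV, in locus order
HAPLOTYPE_COLUMNS = ("a_allele", "b_allele", "drb1_allele", "freq")


class ImputationError(HlaError):
    """Typing cannot be resolved against the haplotype table."""


@dataclass(frozen=True)
class Haplotype:
    a: str
    b: str
    drb1: str
    freq: float

    def allele(self, locus: str) -> str:
        return {"A": self.a, "B": self.b, "DRB1": self.drb1}[locus]


class HaplotypeTable:
    """A~B~DRB1 haplotypes with population frequencies.

    Frequencies must be positive but need not sum to one; they are
    renormalised over the typing-compatible subset at use time.
    """

    def __init__(self, haplotypes: Iterable[Haplotype]):
        self.haplotypes = list(haplotypes)
        seen = set()
        for h in self.haplotypes:
            if h.freq <= 0:
                raise ImputationError(f"haplotype {h.a}~{h.b}~{h.drb1} has non-positive frequency")
            key = (h.a, h.b, h.drb1)
            if key in seen:
                raise ImputationError(f"duplicate haplotype {h.a}~{h.b}~{h.drb1}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HaplotypeTable":
        missing = set(HAPLOTYPE_COLUMNS) - set(df.columns)
        if missing:
            raise ImputationError(f"haplotype table missing columns {sorted(missing)}")
        return cls(
            Haplotype(r.a_allele, r.b_allele, r.drb1_allele, float(r.freq))
            for r in df.itertuples()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "HaplotypeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.a, h.b, h.drb1, h.freq) for h in self.haplotypes],
            columns=list(HAPLOTYPE_COLUMNS),
        )


@dataclass(frozen=True)
class CompletionSet:
    """Genotype completions of one split typing, with normalised weights."""

    typing: SplitTyping
    completions: tuple[tuple[Genotype, float], ...]

    def __len__(self) -> int:
        return len(self.completions)

    @property
    def genotypes(self) -> list[Genotype]:
        return [g for g, _ in self.completions]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.completions])


@dataclass(frozen=True)
class ImputedScore:
    """Frequency-weighted mean and SD of a score over genotype completions."""

    mean: float
    sd: float
    n_completions: int


def enumerate_completions(
    typing: SplitTyping, table: HaplotypeTable, library: AlleleLibrary
) -> CompletionSet:
    """All genotype completions of `typing` under Hardy-Weinberg pairing.

    Every unordered haplotype pair whose combined split projection matches
    the typing contributes weight f1*f2 (doubled when the haplotypes
    differ); weights are renormalised over the compatible set, and pairs
    collapsing to the same genotype are merged.
    """
    haps = table.haplotypes
    # prefilter: each haplotype must project into the typing's antigen sets
    candidates = [
        h
        for h in haps
        if all(library.split_of(h.allele(loc)) in typing.antigens(loc) for loc in LOCI)
    ]

    weights: dict[Genotype, float] = {}
    for i, h1 in enumerate(candidates):
        for h2 in candidates[i:]:
            ok = True
            for locus in LOCI:
                splits = tuple(
                    sorted(
                        (
                            library.split_of(h1.allele(locus)),
                            library.split_of(h2.allele(locus)),
                        )
                    )
                )
                if splits != tuple(sorted(typing.pair(locus))):
                    ok = False
                    break
            if not ok:
                continue
            w = h1.freq * h2.freq
            if (h1.a, h1.b, h1.drb1) != (h2.a, h2.b, h2.drb1):
                w *= 2.0  # heterozygous haplotype pair
            g = Genotype.from_pairs(
                {loc: (h1.allele(loc), h2.allele(loc)) for loc in LOCI}
            )
            weights[g] = weights.get(g, 0.0) + w

    total = sum(weights.values())
    if total <= 0:
        bad = [
            loc
            for loc in LOCI
            if not any(library.split_of(h.allele(loc)) in typing.antigens(loc) for h in haps)
        ]
        raise ImputationError(
            "unresolvable typing: no compatible haplotype pair"
            + (f" (no haplotype covers loci {bad})" if bad else "")
        )
    completions = tuple(
        sorted(((g, w / total) for g, w in weights.items()), key=lambda gw: gw[0].unique_allele_names())
    )
    return CompletionSet(typing=typing, completions=completions)


def imputed_pair_score(
    donor: SplitTyping,
    recipient: SplitTyping,
    table: HaplotypeTable,
    library: AlleleLibrary,
    scorer: Callable[[Genotype, Genotype], float],
) -> ImputedScore:
    """Frequency-weighted mean and SD of the score over all genotype pairs.

    Donor and recipient completions are enumerated independently and
    combined as a product distribution (no linkage is assumed between two
    individuals).
    """
    d_set = enumerate_completions(donor, table, library)
    r_set = enumerate_completions(recipient, table, library)
    weighted: list[tuple[float, float]] = [
        (dw * rw, float(scorer(dg, rg)))
        for dg, dw in d_set.completions
        for rg, rw in r_set.completions
    ]
    mean = sum(w * s for w, s in weighted)
    # central-moment form: stable when the score barely varies
    var = sum(w * (s - mean) ** 2 for w, s in weighted)
    return ImputedScore(mean=mean, sd=math.sqrt(max(var, 0.0)), n_completions=len(weighted))


DONOR_TYPING_COLUMNS = ("donor_a1", "donor_a2", "donor_b1", "donor_b2", "donor_dr1", "donor_dr2")
RECIPIENT_TYPING_COLUMNS = (
    "recipient_a1",
    "recipient_a2",
    "recipient_b1",
    "recipient_b2",
    "recipient_dr1",
    "recipient_dr2",
)


def score_cohort(
    cohort: pd.DataFrame,
    table: HaplotypeTable,
    library: AlleleLibrary,
    scorer: Callable[[Genotype, Genotype], float],
) -> pd.DataFrame:
    """Impute epitope scores and mismatch counts for every cohort row.

    Expects donor/recipient split-typing columns
    (``donor_a1..donor_dr2``, ``recipient_a1..recipient_dr2``) and returns
    a copy with ``pirche_mean``, ``pirche_sd``, ``n_completions``,
    ``hla_mm`` and ``score_error`` appended. Rows whose typing cannot be
    resolved are flagged in ``score_error``, never dropped. Results are
    cached per distinct (donor typing, recipient typing) pair.
    """
    for col in DONOR_TYPING_COLUMNS + RECIPIENT_TYPING_COLUMNS:
        if col not in cohort.columns:
            raise ImputationError(f"cohort is missing typing column {col!r}")

    out = cohort.copy()
    cache: dict[tuple, tuple[float, float, int, int] | str] = {}
    means, sds, ns, mms, errs = [], [], [], [], []
    for row in cohort.itertuples():
        key = tuple(getattr(row, c) for c in DONOR_TYPING_COLUMNS + RECIPIENT_TYPING_COLUMNS)
        res = cache.get(key)
        if res is None:
            try:
                d_typing = parse_split_typing(key[:6], library)
                r_typing = parse_split_typing(key[6:], library)
                imputed = imputed_pair_score(d_typing, r_typing, table, library, scorer)
                mm = count_hla_mismatches(d_typing, r_typing).total
                res = (imputed.mean, imputed.sd, imputed.n_completions, mm)
            except HlaError as exc:
                res = str(exc)
            cache[key] = res
        if isinstance(res, str):
            means.append(np.nan)
            sds.append(np.nan)
            ns.append(0)
            mms.append(np.nan)
            errs.append(res)
        else:
            means.append(res[0])
            sds.append(res[1])
            ns.append(res[2])
            mms.append(res[3])
            errs.append("")
    out["pirche_mean"] = means
    out["pirche_sd"] = sds
    out["n_completions"] = ns
    out["hla_mm"] = mms
    out["score_error"] = errs
    return out
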