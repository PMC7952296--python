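"""Genotype completion enumeration and frequency-weighted score statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from epimatch.hla import AlleleLibrary, Genotype, SplitTyping
from epimatch.imputation import (
    Haplotype,
    HaplotypeTable,
    ImputationError,
    enumerate_completions,
    imputed_pair_score,
    score_cohort,
)

from conftest import allele


def typing(a, b="B1", dr="DR1"):
    pair = lambda x: (x, x) if isinstance(x, str) else tuple(x)
    return SplitTyping.from_pairs({"A": pair(a), "B": pair(b), "DRB1": pair(dr)})


class TestEnumerateCompletions:
    def test_single_compatible_pair_gets_weight_one(self, three_hap_table):
        library, table = three_hap_table
        cs = enumerate_completions(typing("A2"), table, library)
        assert len(cs) == 1
        assert cs.completions[0][1] == pytest.approx(1.0)
        assert cs.completions[0][0].a == ("A*02:01", "A*02:01")

    def test_two_heterozygous_pairs_weighted_by_frequency_products(
        self, three_hap_table
    ):
        # typing A1/A2 is compatible with (h1,h3) and (h2,h3);
        # hand normalization of the HWE weighting:
        #   w1 = 2*0.5*0.2, w2 = 2*0.3*0.2  ->  0.625 / 0.375
        library, table = three_hap_table
        cs = enumerate_completions(typing(("A1", "A2")), table, library)
        got = {g.a: w for g, w in cs.completions}
        assert got[("A*01:01", "A*02:01")] == pytest.approx(0.625)
        assert got[("A*01:02", "A*02:01")] == pytest.approx(0.375)

    def test_homozygous_typing_mixes_hwe_pair_weights(self, three_hap_table):
        # A1/A1: pairs (h1,h1)=0.25, (h1,h2)=2*0.15, (h2,h2)=0.09, total 0.64
        library, table = three_hap_table
        cs = enumerate_completions(typing("A1"), table, library)
        got = {g.a: w for g, w in cs.completions}
        assert got[("A*01:01", "A*01:01")] == pytest.approx(0.25 / 0.64)
        assert got[("A*01:01", "A*01:02")] == pytest.approx(0.30 / 0.64)
        assert got[("A*01:02", "A*01:02")] == pytest.approx(0.09 / 0.64)

    def test_antigen_absent_from_table_is_unresolvable(self, three_hap_table):
        library, table = three_hap_table
        with pytest.raises(ImputationError, match="unresolvable"):
            enumerate_completions(typing("A3"), table, library)

    def test_weights_sum_to_one_over_random_tables(self, three_hap_table):
        library, _ = three_hap_table
        rng = np.random.default_rng(4)
        a_alleles = ["A*01:01", "A*01:02", "A*02:01"]
        for _ in range(50):
            k = int(rng.integers(2, 6))
            rows, seen = [], set()
            for _ in range(k):
                a = a_alleles[rng.integers(3)]
                key = (a, "B*01:01", "DRB1*01:01")
                if key in seen:
                    continue
                seen.add(key)
                rows.append(Haplotype(*key, float(rng.uniform(0.05, 1.0))))
            table = HaplotypeTable(rows)
            splits = sorted({library.split_of(r.a) for r in rows})
            pick = (
                splits[rng.integers(len(splits))],
                splits[rng.integers(len(splits))],
            )
            try:
                cs = enumerate_completions(typing(pick), table, library)
            except ImputationError:
                continue
            assert cs.weights.sum() == pytest.approx(1.0, abs=1e-9)
            for g, _ in cs.completions:
                assert tuple(sorted(library.split_of(n) for n in g.a)) == tuple(
                    sorted(pick)
                )


class TestImputedPairScore:
    def test_single_completions_give_exact_score_sd_zero(self, three_hap_table):
        library, table = three_hap_table
        score = lambda d, r: 42.0
        res = imputed_pair_score(typing("A2"), typing("A2"), table, library, score)
        assert res.mean == pytest.approx(42.0)
        assert res.sd == 0.0
        assert res.n_completions == 1

    def test_two_equiprobable_scores_mean_and_sd_by_hand(self):
        # donor completions 50/50 between two genotypes scoring 10 and 20:
        # mean 15, sd 5 by direct weighted moments
        library = AlleleLibrary(
            [
                allele("A", "A*01:01", "A1"),
                allele("A", "A*01:02", "A1"),
                allele("A", "A*02:01", "A2"),
                allele("A", "A*03:01", "A3"),
                allele("B", "B*01:01", "B1"),
                allele("DRB1", "DRB1*01:01", "DR1"),
            ]
        )
        table = HaplotypeTable(
            [
                Haplotype("A*01:01", "B*01:01", "DRB1*01:01", 0.2),
                Haplotype("A*01:02", "B*01:01", "DRB1*01:01", 0.2),
                Haplotype("A*02:01", "B*01:01", "DRB1*01:01", 0.2),
                Haplotype("A*03:01", "B*01:01", "DRB1*01:01", 0.2),
            ]
        )

        def score(d, r):
            return 10.0 if d.a == ("A*01:01", "A*02:01") else 20.0

        res = imputed_pair_score(
            typing(("A1", "A2")), typing("A3"), table, library, score
        )
        assert res.mean == pytest.approx(15.0)
        assert res.sd == pytest.approx(5.0)
        assert res.n_completions == 2

    def test_identical_self_scoring_completions_give_zero_mean(self, three_hap_table):
        library, table = three_hap_table
        score = lambda d, r: 0.0 if d == r else 99.0
        res = imputed_pair_score(typing("A2"), typing("A2"), table, library, score)
        assert res.mean == 0.0

    def test_mean_matches_exhaustive_ordered_enumeration(self, three_hap_table):
        """Oracle: expectation over all ordered 4-tuples of haplotypes."""
        library, table = three_hap_table

        def score(d, r):  # arbitrary deterministic score
            return float(len(set(d.a) ^ set(r.a))) * 3.0 + float(d.a == r.a)

        d_typing, r_typing = typing(("A1", "A2")), typing("A1")
        res = imputed_pair_score(d_typing, r_typing, table, library, score)

        def compatible(h1, h2, t):
            return tuple(
                sorted((library.split_of(h1.a), library.split_of(h2.a)))
            ) == tuple(sorted(t.pair("A")))

        haps = table.haplotypes
        num = den = num2 = 0.0
        for h1 in haps:
            for h2 in haps:
                if not compatible(h1, h2, d_typing):
                    continue
                dg = Genotype.from_pairs(
                    {"A": (h1.a, h2.a), "B": (h1.b, h2.b), "DRB1": (h1.drb1, h2.drb1)}
                )
                for h3 in haps:
                    for h4 in haps:
                        if not compatible(h3, h4, r_typing):
                            continue
                        rg = Genotype.from_pairs(
                            {
                                "A": (h3.a, h4.a),
                                "B": (h3.b, h4.b),
                                "DRB1": (h3.drb1, h4.drb1),
                            }
                        )
                        w = h1.freq * h2.freq * h3.freq * h4.freq
                        s = score(dg, rg)
                        num += w * s
                        num2 += w * s * s
                        den += w
        mean = num / den
        sd = math.sqrt(max(num2 / den - mean * mean, 0.0))
        assert res.mean == pytest.approx(mean, rel=1e-12)
        assert res.sd == pytest.approx(sd, rel=1e-9)

    def test_sd_invariant_when_frequency_split_across_equivalent_allele(self):
        """Splitting a haplotype's frequency onto a same-sequence allele
        changes the completion bookkeeping but not the score distribution."""
        seq = "ACDEFGHIKLMNPQRSTVWY"
        base = [
            allele("A", "A*01:01", "A1", seq),
            allele("A", "A*02:01", "A2"),
            allele("B", "B*01:01", "B1"),
            allele("DRB1", "DRB1*01:01", "DR1"),
        ]
        lib_a = AlleleLibrary(base)
        lib_b = AlleleLibrary(base + [allele("A", "A*01:05", "A1", seq)])
        table_a = HaplotypeTable(
            [
                Haplotype("A*01:01", "B*01:01", "DRB1*01:01", 0.4),
                Haplotype("A*02:01", "B*01:01", "DRB1*01:01", 0.6),
            ]
        )
        table_b = HaplotypeTable(
            [
                Haplotype("A*01:01", "B*01:01", "DRB1*01:01", 0.25),
                Haplotype("A*01:05", "B*01:01", "DRB1*01:01", 0.15),
                Haplotype("A*02:01", "B*01:01", "DRB1*01:01", 0.6),
            ]
        )

        def make_score(lib):
            def score(d, r):  # depends on sequences only, not on names
                return float(
                    sum(len(lib.get(n).protein) for n in d.unique_allele_names())
                    - sum(len(lib.get(n).protein) for n in r.unique_allele_names())
                ) ** 2

            return score

        d_t, r_t = typing(("A1", "A2")), typing("A2")
        res_a = imputed_pair_score(d_t, r_t, table_a, lib_a, make_score(lib_a))
        res_b = imputed_pair_score(d_t, r_t, table_b, lib_b, make_score(lib_b))
        assert res_b.mean == pytest.approx(res_a.mean, rel=1e-12)
        assert res_b.sd == pytest.approx(res_a.sd, abs=1e-9)


class TestScoreCohort:
    def make_cohort(self):
        row = dict(
            donor_a1="A1", donor_a2="A2", donor_b1="B1", donor_b2="B1",
            donor_dr1="DR1", donor_dr2="DR1",
            recipient_a1="A1", recipient_a2="A1", recipient_b1="B1",
            recipient_b2="B1", recipient_dr1="DR1", recipient_dr2="DR1",
        )
        return pd.DataFrame([row, row, {**row, "donor_a1": "A2", "donor_a2": "A2"}])

    def test_identical_typing_pairs_hit_the_cache(self, three_hap_table):
        library, table = three_hap_table
        calls = []

        def score(d, r):
            calls.append((d, r))
            return 1.0

        out = score_cohort(self.make_cohort(), table, library, score)
        assert (out["score_error"] == "").all()
        # rows 1 and 2 share a typing pair: their completion products are
        # evaluated once
        assert len(calls) == len(set(calls))
        assert out["hla_mm"].tolist() == [1, 1, 1]

    def test_unresolvable_row_is_flagged_not_dropped(self, three_hap_table):
        library, table = three_hap_table
        cohort = self.make_cohort()
        cohort.loc[2, "donor_a1"] = "A3"
        cohort.loc[2, "donor_a2"] = "A3"
        out = score_cohort(cohort, table, library, lambda d, r: 1.0)
        assert len(out) == 3
        assert (out.loc[0:1, "score_error"] == "").all()
        assert "unresolvable" in out.loc[2, "score_error"]
        assert np.isnan(out.loc[2, "pirche_mean"])

    def test_hla_identical_pairs_all_score_zero(self, three_hap_table):
        # A2 typings resolve to a single completion, so donor and recipient
        # genotypes coincide exactly and every product pair is self-identical
        library, table = three_hap_table
        cohort = self.make_cohort().assign(
            donor_a1="A2", donor_a2="A2", recipient_a1="A2", recipient_a2="A2"
        )
        out = score_cohort(
            cohort, table, library, lambda d, r: 0.0 if d == r else 7.0
        )
        assert (out["pirche_mean"] == 0.0).all()
        assert (out["hla_mm"] == 0).all()
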