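import numpy as np
import pytest

from epimatch.epitopes import PwmPredictor, PresentationCall
from epimatch.hla import AlleleLibrary, AlleleRecord, Genotype
from epimatch.imputation import Haplotype, HaplotypeTable

# a short protein (<15 residues) contributes no peptides at all
STUB = "ACDEFGHIK"


def allele(locus, name, split, protein=STUB):
    return AlleleRecord(locus=locus, name=name, split=split, protein=protein)


@pytest.fixture
def stub_library():
    """Minimal library: one allele per locus, proteins too short to yield peptides."""
    return AlleleLibrary(
        [
            allele("A", "A*01:01", "A1"),
            allele("B", "B*01:01", "B1"),
            allele("DRB1", "DRB1*01:01", "DR1"),
        ]
    )


class FixedCorePredictor:
    """Deterministic test predictor: always presents, core at a fixed offset."""

    def __init__(self, core_start=3, presented=True):
        self.core_start = core_start
        self.presented = presented

    def predict(self, peptide, presenter):
        core = peptide[self.core_start : self.core_start + 9]
        if not self.presented:
            return PresentationCall(False, None, presenter.name, 0.0)
        return PresentationCall(True, core, presenter.name, 1.0)


@pytest.fixture
def fixed_core_predictor():
    return FixedCorePredictor()


@pytest.fixture
def three_hap_table():
    """Toy imputation setting: three A-locus splits over a shared B~DR backbone."""
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
            Haplotype("A*01:01", "B*01:01", "DRB1*01:01", 0.5),
            Haplotype("A*01:02", "B*01:01", "DRB1*01:01", 0.3),
            Haplotype("A*02:01", "B*01:01", "DRB1*01:01", 0.2),
        ]
    )
    return library, table


def random_toy_library(rng, alphabet="ACDEFG", min_len=20, max_len=60):
    """Random two-allele-per-locus library over a reduced amino-acid alphabet."""
    letters = np.array(list(alphabet))
    records = []
    splits = {"A": "A", "B": "B", "DRB1": "DR"}
    for locus in ("A", "B", "DRB1"):
        for j in (1, 2):
            length = int(rng.integers(min_len, max_len + 1))
            seq = "".join(letters[rng.integers(len(letters), size=length)])
            records.append(
                AlleleRecord(
                    locus=locus,
                    name=f"{locus}*{j:02d}:01",
                    split=f"{splits[locus]}{j}",
                    protein=seq,
                )
            )
    return AlleleLibrary(records)


def random_pwm(rng, library, alphabet="ACDEFG", threshold=1.0):
    matrices = {
        rec.name: rng.normal(0.0, 1.0, size=(9, len(alphabet)))
        for rec in library.alleles_at("DRB1")
    }
    return PwmPredictor(matrices, threshold=threshold, alphabet=alphabet)


def random_genotype(rng, library):
    pairs = {}
    for locus in ("A", "B", "DRB1"):
        names = [r.name for r in library.alleles_at(locus)]
        pairs[locus] = (names[rng.integers(len(names))], names[rng.integers(len(names))])
    return Genotype.from_pairs(pairs)
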