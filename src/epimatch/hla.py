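"""Core HLA domain objects.

Allele libraries (two-field alleles with their serological split-antigen
labels and exon-2-5 protein sequences), split-level typings, molecular
genotypes, and antigen-level mismatch counting over HLA-A, -B and -DRB1.

Mismatch convention: at each locus the count is the number of *unique*
donor split antigens absent from the recipient's antigens at that locus
(Eurotransplant-style donor-antigen-not-in-recipient counting, maximum
two per locus, so totals range 0-6). A homozygous donor antigen that the
recipient lacks counts once, not twice. Split labels are opaque strings
matched exactly; no broad/split hierarchy is resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

LOCI: tuple[str, ...] = ("A", "B", "DRB1")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALLELE_NAME_RE = re.compile(r"^([A-Z][A-Z0-9]*)\*(\d{2,}):(\d{2,})$")


class HlaError(ValueError):
    """Invalid HLA input (library, typing or genotype)."""


class LibraryError(HlaError):
    """Problem building or querying an allele library."""


class TypingError(HlaError):
    """Malformed or unresolvable split typing."""


@dataclass(frozen=True)
class AlleleRecord:
    """One two-field HLA allele.

    Parameters
    ----------
    locus : str
        Gene locus, e.g. ``"A"``, ``"B"`` or ``"DRB1"``.
    name : str
        Two-field allele label, e.g. ``"A*02:01"``.
    split : str
        Serological split-antigen label, e.g. ``"A2"``.
    protein : str
        Amino-acid sequence of the exon-2-5 encoded region.
    """

    locus: str
    name: str
    split: str
    protein: str

    def __post_init__(self) -> None:
        m = _ALLELE_NAME_RE.match(self.name)
        if m is None:
            raise LibraryError(
                f"allele name {self.name!r} is not a two-field label "
                "(expected LOCUS*FF:FF)"
            )
        if m.group(1) != self.locus:
            raise LibraryError(
                f"allele {self.name!r} does not belong to locus {self.locus!r}"
            )
        if not self.split:
            raise LibraryError(f"allele {self.name} has an empty split label")
        if not self.protein:
            raise LibraryError(f"allele {self.name} has an empty protein sequence")
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise LibraryError(
                f"allele {self.name} protein contains non-amino-acid "
                f"characters {sorted(bad)!r}"
            )


class AlleleLibrary:
    """A validated collection of :class:`AlleleRecord`, unique by name."""

    def __init__(self, records: Iterable[AlleleRecord]):
        self._records: dict[str, AlleleRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise LibraryError(f"duplicate allele {rec.name} in library")
            self._records[rec.name] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AlleleRecord]:
        return iter(self._records.values())

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def get(self, name: str) -> AlleleRecord:
        try:
            return self._records[name]
        except KeyError:
            raise LibraryError(f"allele {name!r} not in library") from None

    def alleles_at(self, locus: str) -> list[AlleleRecord]:
        return [r for r in self._records.values() if r.locus == locus]

    def split_of(self, name: str) -> str:
        return self.get(name).split

    def splits_at(self, locus: str) -> set[str]:
        return {r.split for r in self._records.values() if r.locus == locus}

    def valid_splits(self) -> dict[str, set[str]]:
        """Split labels known per locus, for typing validation."""
        out: dict[str, set[str]] = {}
        for rec in self._records.values():
            out.setdefault(rec.locus, set()).add(rec.split)
        return out


def load_allele_library(fasta_path: str | Path, split_map_path: str | Path) -> AlleleLibrary:
    """Load an allele library from a FASTA file and an allele->split CSV.

    FASTA headers must start with the two-field allele name
    (``>A*02:01 optional description``); the locus is taken from the name.
    The split map must cover every allele in the FASTA
    (columns ``allele,split``).
    """
    split_map = pd.read_csv(split_map_path, dtype=str)
    if not {"allele", "split"}.issubset(split_map.columns):
        raise LibraryError("split map needs columns 'allele' and 'split'")
    split_of = dict(
        zip(split_map["allele"].str.upper().str.strip(), split_map["split"].str.strip())
    )

    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = seq_rec.id.strip().upper()
        m = _ALLELE_NAME_RE.match(name)
        if m is None:
            raise LibraryError(f"FASTA header {seq_rec.id!r} is not a two-field allele name")
        if name not in split_of:
            raise LibraryError(f"allele {name} has no split-antigen mapping")
        records.append(
            AlleleRecord(
                locus=m.group(1),
                name=name,
                split=split_of[name],
                protein=str(seq_rec.seq).upper(),
            )
        )
    return AlleleLibrary(records)


def _unordered(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SplitTyping:
    """Split-antigen typing at HLA-A, -B and -DRB1.

    Each locus carries an unordered pair of split labels; a homozygous
    typing repeats the same label.
    """

    a: tuple[str, str]
    b: tuple[str, str]
    drb1: tuple[str, str]

    def pair(self, locus: str) -> tuple[str, str]:
        return {"A": self.a, "B": self.b, "DRB1": self.drb1}[locus]

    def antigens(self, locus: str) -> set[str]:
        return set(self.pair(locus))

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, Sequence[str]]) -> "SplitTyping":
        missing = set(LOCI) - set(pairs)
        if missing:
            raise TypingError(f"typing missing loci {sorted(missing)}")
        return cls(
            a=_unordered(pairs["A"]),
            b=_unordered(pairs["B"]),
            drb1=_unordered(pairs["DRB1"]),
        )


def parse_split_typing(
    fields: Sequence[str], library: AlleleLibrary | Mapping[str, set[str]]
) -> SplitTyping:
    """Parse six typing fields (A1,A2,B1,B2,DR1,DR2) into a :class:`SplitTyping`.

    A blank second field at a locus means homozygous. Labels are validated
    against the splits known to `library` (an :class:`AlleleLibrary` or a
    locus -> {split} mapping).
    """
    if len(fields) != 6:
        raise TypingError(f"expected 6 typing fields, got {len(fields)}")
    valid = library.valid_splits() if isinstance(library, AlleleLibrary) else library

    def _norm(x: object) -> str:
        s = "" if x is None or (isinstance(x, float) and pd.isna(x)) else str(x).strip()
        return s

    pairs: dict[str, tuple[str, str]] = {}
    for locus, (f1, f2) in zip(LOCI, [fields[0:2], fields[2:4], fields[4:6]]):
        first, second = _norm(f1), _norm(f2)
        if not first and second:
            first, second = second, ""
        if not first:
            raise TypingError(f"locus {locus} has no typing")
        if not second:
            second = first  # homozygous
        for label in (first, second):
            if label not in valid.get(locus, set()):
                raise TypingError(f"unknown split label {label!r} at locus {locus}")
        pairs[locus] = (first, second)
    return SplitTyping.from_pairs(pairs)


@dataclass(frozen=True)
class Genotype:
    """Two-field molecular genotype: an unordered allele pair per locus.

    Alleles are referenced by name; sequences live in the library.
    """

    a: tuple[str, str]
    b: tuple[str, str]
    drb1: tuple[str, str]

    def pair(self, locus: str) -> tuple[str, str]:
        return {"A": self.a, "B": self.b, "DRB1": self.drb1}[locus]

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, Sequence[str]]) -> "Genotype":
        return cls(
            a=_unordered(pairs["A"]),
            b=_unordered(pairs["B"]),
            drb1=_unordered(pairs["DRB1"]),
        )

    def unique_allele_names(self, loci: Sequence[str] = LOCI) -> tuple[str, ...]:
        names: set[str] = set()
        for locus in loci:
            names.update(self.pair(locus))
        return tuple(sorted(names))

    def split_typing(self, library: AlleleLibrary) -> SplitTyping:
        return SplitTyping.from_pairs(
            {locus: tuple(library.split_of(n) for n in self.pair(locus)) for locus in LOCI}
        )


@dataclass(frozen=True)
class MismatchCount:
    """Antigen mismatches per locus (0-2 each) and in total (0-6)."""

    per_locus: tuple[tuple[str, int], ...]
    total: int

    def at(self, locus: str) -> int:
        return dict(self.per_locus)[locus]


def count_hla_mismatches(donor: SplitTyping, recipient: SplitTyping) -> MismatchCount:
    """Count donor split antigens absent from the recipient, per locus and total.

    Unique-antigen counting: a homozygous donor antigen missing from the
    recipient contributes one mismatch, and each locus contributes at most
    two, so the total lies in 0-6.
    """
    per = []
    total = 0
    for locus in LOCI:
        n = len(donor.antigens(locus) - recipient.antigens(locus))
        per.append((locus, n))
        total += n
    return MismatchCount(per_locus=tuple(per), total=total)
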