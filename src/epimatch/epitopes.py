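"""Epitope-load scoring core.

The score counts donor-derived 15-mer peptides that (a) do not occur in
the recipient's own HLA protein repertoire and (b) are predicted to be
presented by one of the recipient's HLA-DRB1 molecules — a model of the
indirect pathway of CD4+ T-cell allorecognition. Presented peptides are
deduplicated by their 9-amino-acid binding core: identical cores arising
from different donor 15-mers are counted once per presenting DRB1
protein.

The presentation predictor is a pluggable contract. The bundled
position-weight-matrix (PWM) predictor is a deliberately simple,
deterministic stand-in for trained MHC class II predictors; the scoring
chain around it does not depend on which predictor is plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import yaml

from .hla import LOCI, AlleleLibrary, AlleleRecord, Genotype, HlaError

PEPTIDE_LENGTH = 15
CORE_LENGTH = 9
#: windows of length 9 inside a 15-mer
N_CORE_WINDOWS = PEPTIDE_LENGTH - CORE_LENGTH + 1

AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_SELF_LOCI: tuple[str, ...] = LOCI
DEFAULT_DONOR_LOCI: tuple[str, ...] = LOCI


class PredictorError(HlaError):
    """Presentation predictor could not evaluate a (peptide, allele) pair."""


@dataclass(frozen=True)
class Peptide15:
    """A 15-mer window of an HLA protein, with its provenance."""

    sequence: str
    source_allele: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide must have length {PEPTIDE_LENGTH}")


@dataclass(frozen=True)
class PresentationCall:
    """Outcome of one presentation prediction.

    ``core`` is the 9-mer binding core chosen within the 15-mer; it is
    only defined when ``presented`` is true.
    """

    presented: bool
    core: str | None
    presenter: str
    affinity_score: float

    def __post_init__(self) -> None:
        if self.presented and (self.core is None or len(self.core) != CORE_LENGTH):
            raise ValueError("presented call requires a 9-mer core")


class PresentationPredictor(Protocol):
    """Contract: deterministic (15-mer, DRB1 allele) -> PresentationCall."""

    def predict(self, peptide: str, presenter: AlleleRecord) -> PresentationCall: ...


def enumerate_15mers(protein: str, source_allele: str = "") -> list[Peptide15]:
    """All 15-mer windows of `protein` at stride 1, in order.

    Duplicates are retained; deduplication happens at scoring time. A
    protein shorter than 15 residues yields an empty list.
    """
    return [
        Peptide15(protein[i : i + PEPTIDE_LENGTH], source_allele, i)
        for i in range(len(protein) - PEPTIDE_LENGTH + 1)
    ]


def self_peptidome(
    recipient: Genotype,
    library: AlleleLibrary,
    self_loci: Sequence[str] = DEFAULT_SELF_LOCI,
) -> set[str]:
    """Union of all 15-mers of the recipient's proteins at the self loci."""
    peptides: set[str] = set()
    for locus in self_loci:
        for name in set(recipient.pair(locus)):
            protein = library.get(name).protein
            for i in range(len(protein) - PEPTIDE_LENGTH + 1):
                peptides.add(protein[i : i + PEPTIDE_LENGTH])
    return peptides


class PwmPredictor:
    """Position-weight-matrix presentation predictor.

    Each DRB1 allele has a 9-position x 20-residue weight matrix. A
    15-mer's seven 9-mer windows are scored by summing per-position
    weights; the maximal window (leftmost on ties) is the binding core,
    and the peptide is presented iff that maximum reaches `threshold`.
    Deterministic by construction; calls are memoised.
    """

    def __init__(
        self,
        matrices: Mapping[str, np.ndarray],
        threshold: float,
        alphabet: str = AA20,
    ):
        self.alphabet = alphabet
        self._index = {aa: i for i, aa in enumerate(alphabet)}
        self.matrices = {}
        for name, m in matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (CORE_LENGTH, len(alphabet)):
                raise ValueError(
                    f"PWM for {name} must be {CORE_LENGTH}x{len(alphabet)}, got {m.shape}"
                )
            self.matrices[name] = m
        self.threshold = float(threshold)
        self._cache: dict[tuple[str, str], PresentationCall] = {}

    def window_score(self, window: str, presenter_name: str) -> float:
        """Score one 9-mer against one allele's matrix."""
        m = self.matrices[presenter_name]
        idx = self._index
        return float(sum(m[pos][idx[aa]] for pos, aa in enumerate(window)))

    def predict(self, peptide: str, presenter: AlleleRecord) -> PresentationCall:
        name = presenter.name
        if name not in self.matrices:
            raise PredictorError(f"no PWM for presenter {name}")
        key = (peptide, name)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        best_score = -np.inf
        best_core = None
        for start in range(N_CORE_WINDOWS):
            window = peptide[start : start + CORE_LENGTH]
            s = self.window_score(window, name)
            if s > best_score:  # strict: leftmost wins ties
                best_score = s
                best_core = window
        presented = best_score >= self.threshold
        call = PresentationCall(
            presented=presented,
            core=best_core if presented else None,
            presenter=name,
            affinity_score=best_score,
        )
        self._cache[key] = call
        return call

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "alphabet": self.alphabet,
            "threshold": self.threshold,
            "matrices": {k: m.tolist() for k, m in self.matrices.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PwmPredictor":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            matrices={k: np.asarray(v) for k, v in payload["matrices"].items()},
            threshold=payload["threshold"],
            alphabet=payload["alphabet"],
        )


def toy_pwm_predictor(pwm_config: str | Path | Mapping) -> PwmPredictor:
    """Build a :class:`PwmPredictor` from a YAML file or an in-memory mapping."""
    if isinstance(pwm_config, (str, Path)):
        return PwmPredictor.from_yaml(pwm_config)
    return PwmPredictor(
        matrices={k: np.asarray(v) for k, v in pwm_config["matrices"].items()},
        threshold=pwm_config["threshold"],
        alphabet=pwm_config.get("alphabet", AA20),
    )


@dataclass(frozen=True)
class PircheResult:
    """Raw epitope-load count plus the surviving (core, presenter) set."""

    raw_score: int
    pairs: frozenset[tuple[str, str]]
    per_presenter: tuple[tuple[str, int], ...]

    def breakdown(self) -> dict[str, int]:
        return dict(self.per_presenter)


def pirche_ii_score(
    donor: Genotype,
    recipient: Genotype,
    library: AlleleLibrary,
    predictor: PresentationPredictor,
    self_loci: Sequence[str] = DEFAULT_SELF_LOCI,
    donor_loci: Sequence[str] = DEFAULT_DONOR_LOCI,
    dedup_scope: str = "per_presenter",
) -> PircheResult:
    """Epitope-load score for a donor/recipient genotype pair.

    Pipeline: enumerate 15-mers over the donor's unique allele proteins,
    discard any 15-mer found in the recipient self-peptidome (exact 15-mer
    identity), query the predictor for every surviving peptide against
    every unique recipient DRB1 allele, and count distinct
    (9-mer core, presenter) pairs. With ``dedup_scope="global"`` cores are
    instead pooled across presenters and counted once overall.
    """
    if dedup_scope not in ("per_presenter", "global"):
        raise ValueError("dedup_scope must be 'per_presenter' or 'global'")

    self_set = self_peptidome(recipient, library, self_loci)
    donor_peptides: set[str] = set()
    for name in donor.unique_allele_names(donor_loci):
        protein = library.get(name).protein
        for i in range(len(protein) - PEPTIDE_LENGTH + 1):
            donor_peptides.add(protein[i : i + PEPTIDE_LENGTH])
    survivors = donor_peptides - self_set

    presenters = [library.get(n) for n in sorted(set(recipient.pair("DRB1")))]
    pairs: set[tuple[str, str]] = set()
    for peptide in sorted(survivors):
        for presenter in presenters:
            try:
                call = predictor.predict(peptide, presenter)
            except Exception as exc:  # annotate failure site
                raise PredictorError(
                    f"predictor failed on peptide {peptide} / presenter {presenter.name}: {exc}"
                ) from exc
            if call.presented:
                assert call.core is not None
                pairs.add((call.core, presenter.name))

    if dedup_scope == "global":
        cores = {c for c, _ in pairs}
        raw = len(cores)
    else:
        raw = len(pairs)
    counts: dict[str, int] = {p.name: 0 for p in presenters}
    for _, pres in pairs:
        counts[pres] += 1
    return PircheResult(
        raw_score=raw,
        pairs=frozenset(pairs),
        per_presenter=tuple(sorted(counts.items())),
    )


def brute_force_score(
    donor: Genotype,
    recipient: Genotype,
    library: AlleleLibrary,
    predictor: PresentationPredictor,
    self_loci: Sequence[str] = DEFAULT_SELF_LOCI,
    donor_loci: Sequence[str] = DEFAULT_DONOR_LOCI,
) -> int:
    """Naive re-derivation of the epitope-load count, used as a test oracle.

    Nested loops and list scans only — no sets, no caching, no shared
    helpers with :func:`pirche_ii_score`.
    """
    # recipient repertoire as a plain list
    self_list: list[str] = []
    for locus in self_loci:
        for name in recipient.pair(locus):
            protein = library.get(name).protein
            for i in range(len(protein) - PEPTIDE_LENGTH + 1):
                self_list.append(protein[i : i + PEPTIDE_LENGTH])

    # donor peptides from each distinct allele protein, duplicates allowed
    donor_names: list[str] = []
    for locus in donor_loci:
        for name in donor.pair(locus):
            if name not in donor_names:
                donor_names.append(name)

    presenter_names: list[str] = []
    for name in recipient.pair("DRB1"):
        if name not in presenter_names:
            presenter_names.append(name)

    found: list[tuple[str, str]] = []
    for name in donor_names:
        protein = library.get(name).protein
        for i in range(len(protein) - PEPTIDE_LENGTH + 1):
            pep = protein[i : i + PEPTIDE_LENGTH]
            is_self = False
            for s in self_list:
                if s == pep:
                    is_self = True
                    break
            if is_self:
                continue
            for pname in presenter_names:
                call = predictor.predict(pep, library.get(pname))
                if call.presented:
                    pair = (call.core, pname)
                    seen = False
                    for f in found:
                        if f == pair:
                            seen = True
                            break
                    if not seen:
                        found.append(pair)
    return len(found)


class GenotypePairScorer:
    """Memoised genotype-pair scorer for batch work.

    Caches per-genotype peptide sets, self-peptidomes and pair scores so
    cohort-scale scoring touches the predictor once per distinct
    (peptide, presenter) pair. Scores are deterministic, so caching is
    safe.
    """

    def __init__(
        self,
        library: AlleleLibrary,
        predictor: PresentationPredictor,
        self_loci: Sequence[str] = DEFAULT_SELF_LOCI,
        donor_loci: Sequence[str] = DEFAULT_DONOR_LOCI,
        dedup_scope: str = "per_presenter",
    ):
        self.library = library
        self.predictor = predictor
        self.self_loci = tuple(self_loci)
        self.donor_loci = tuple(donor_loci)
        self.dedup_scope = dedup_scope
        self._donor_peps: dict[Genotype, frozenset[str]] = {}
        self._self_peps: dict[Genotype, frozenset[str]] = {}
        self._scores: dict[tuple[Genotype, Genotype], int] = {}

    def _donor_set(self, g: Genotype) -> frozenset[str]:
        cached = self._donor_peps.get(g)
        if cached is None:
            peps: set[str] = set()
            for name in g.unique_allele_names(self.donor_loci):
                protein = self.library.get(name).protein
                for i in range(len(protein) - PEPTIDE_LENGTH + 1):
                    peps.add(protein[i : i + PEPTIDE_LENGTH])
            cached = frozenset(peps)
            self._donor_peps[g] = cached
        return cached

    def _self_set(self, g: Genotype) -> frozenset[str]:
        cached = self._self_peps.get(g)
        if cached is None:
            cached = frozenset(self_peptidome(g, self.library, self.self_loci))
            self._self_peps[g] = cached
        return cached

    def score(self, donor: Genotype, recipient: Genotype) -> int:
        key = (donor, recipient)
        hit = self._scores.get(key)
        if hit is not None:
            return hit
        survivors = self._donor_set(donor) - self._self_set(recipient)
        presenters = [self.library.get(n) for n in sorted(set(recipient.pair("DRB1")))]
        pairs: set[tuple[str, str]] = set()
        for pep in survivors:
            for presenter in presenters:
                call = self.predictor.predict(pep, presenter)
                if call.presented:
                    pairs.add((call.core, presenter.name))
        if self.dedup_scope == "global":
            raw = len({c for c, _ in pairs})
        else:
            raw = len(pairs)
        self._scores[key] = raw
        return raw

    def __call__(self, donor: Genotype, recipient: Genotype) -> int:
        return self.score(donor, recipient)
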