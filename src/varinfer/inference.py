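"""Iterative greedy parsimony assignment of peptides to variant entries.

The protein inference problem: peptides shared between highly homologous
database entries make search-engine output ambiguous, and naive reporting
either lists redundant sequences or promotes false positives.  The strategy
implemented here explains all observed peptides with the lowest possible
number of protein entries (Occam's razor):

1. select the candidate entry matching the largest number of remaining
   distinct peptides (documented tie-breaking);
2. remove from candidacy every entry whose remaining peptides are the same
   set or a fraction (subset) of the selected entry's peptides, recording
   them as pruned by subsumption;
3. remove the assigned peptides and repeat until every peptide is assigned.

A policy-driven evidence-pruning pass then removes selected entries whose
distinguishing evidence (peptides no other selected entry contains) rests on
too few acceptable spectra — the automated analogue of manually discarding
variants suggested on the basis of one spectrum of doubtful reliability.
An exhaustive minimum-set-cover oracle validates the parsimony objective on
small instances, and grouping-scenario classification labels the ambiguity
structure of the incidence matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .psm import PSM, IncidenceMatrix
from .variantdb import VariantEntry


class InferenceError(ValueError):
    """Raised for invalid inference inputs."""


@dataclass(frozen=True)
class SelectedVariant:
    """One selected entry with its disjointly assigned peptides."""

    accession: str
    peptides: tuple[str, ...]
    round: int


@dataclass
class InferenceResult:
    """Minimal explaining variant set with evidence and audit trail."""

    selected: list[SelectedVariant]
    evidence_class: dict[str, str] = field(default_factory=dict)
    pruned: list[tuple[str, str]] = field(default_factory=list)
    coverage: dict[str, float] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    @property
    def accessions(self) -> list[str]:
        return [s.accession for s in self.selected]

    def assigned(self, accession: str) -> tuple[str, ...]:
        for s in self.selected:
            if s.accession == accession:
                return s.peptides
        raise KeyError(accession)

    def to_rows(self) -> list[dict]:
        rows = []
        for s in self.selected:
            unique = self.evidence_class.get(s.accession, "")
            rows.append({
                "accession": s.accession,
                "round": s.round,
                "n_peptides": len(s.peptides),
                "evidence_class": unique,
                "coverage_pct": round(self.coverage.get(s.accession, float("nan")), 1)
                if s.accession in self.coverage else "",
                "peptides": ";".join(s.peptides),
            })
        return rows


@dataclass(frozen=True)
class PruningPolicy:
    """Operationalisation of "doubtful reliability" for unique evidence.

    ``min_unique_psms``: minimum number of acceptable PSMs supporting an
    entry's distinguishing peptides (default 2 auto-prunes single-spectrum
    identifications; 1 reproduces manual mode, retaining them with a
    review flag).  ``score_floor``: PSMs scoring below it count as doubtful.
    ``accept_tier2_unique``: whether pass-two PSMs may count as acceptable
    unique evidence.
    """

    min_unique_psms: int = 2
    score_floor: float = 0.0
    accept_tier2_unique: bool = False

    def __post_init__(self) -> None:
        if self.min_unique_psms < 1:
            raise InferenceError("min_unique_psms must be >= 1")

    def acceptable(self, psm: PSM) -> bool:
        if psm.tier == 2 and not self.accept_tier2_unique:
            return False
        return psm.score >= self.score_floor


def _covered_positions(sequence: str, peptides: Iterable[str]) -> set[int]:
    covered: set[int] = set()
    for peptide in peptides:
        start = sequence.find(peptide)
        if start < 0:
            raise InferenceError(
                f"peptide {peptide!r} not locatable on sequence")
        while start >= 0:
            covered.update(range(start, start + len(peptide)))
            start = sequence.find(peptide, start + 1)
    return covered


def sequence_coverage(variant, peptides: Iterable) -> float:
    """Percent of a protein's residues covered by >= 1 assigned peptide.

    *variant* may be a :class:`~varinfer.variantdb.VariantEntry` or a bare
    sequence string; *peptides* an iterable of peptide sequence strings (or
    objects with a ``sequence`` attribute).  Overlapping peptides count each
    residue once; every occurrence of a repeated peptide counts.
    """
    sequence = variant.sequence if hasattr(variant, "sequence") else variant
    seqs = [p.sequence if hasattr(p, "sequence") else p for p in peptides]
    if not seqs:
        return 0.0
    covered = _covered_positions(sequence, seqs)
    return 100.0 * len(covered) / len(sequence)


def _selection_key(inc: IncidenceMatrix, accession: str,
                   remaining: frozenset) -> tuple:
    """Sort key for candidate selection (used with min()).

    Primary: most remaining peptides matched.  Ties: larger summed PSM score
    over those peptides, then larger potential sequence coverage, then
    lexicographically smaller accession.
    """
    peptides = inc.peptide_set(accession) & remaining
    score = sum(p.score for pep in peptides for p in inc.psm_support[pep])
    if accession in inc.sequences and peptides:
        coverage = sequence_coverage(inc.sequences[accession], peptides)
    else:
        coverage = 0.0
    return (-len(peptides), -score, -coverage, accession)


def greedy_parsimony(inc: IncidenceMatrix) -> InferenceResult:
    """Iterative greedy selection of the minimal explaining variant set.

    An empty incidence matrix yields an empty result.  Assigned peptide sets
    are pairwise disjoint and jointly exhaust every peptide that at least
    one variant can explain; unexplainable rows are reported as unassigned.
    """
    explainable = [p for i, p in enumerate(inc.peptides)
                   if inc.membership[i].any()]
    unassigned = [p for i, p in enumerate(inc.peptides)
                  if not inc.membership[i].any()]
    remaining = frozenset(explainable)
    candidates = [v for v in inc.variants if inc.peptide_set(v) & remaining]

    selected: list[SelectedVariant] = []
    pruned: list[tuple[str, str]] = []
    round_no = 0
    row_order = {p: i for i, p in enumerate(inc.peptides)}
    while remaining:
        round_no += 1
        best = min(candidates,
                   key=lambda v: _selection_key(inc, v, remaining))
        assigned = inc.peptide_set(best) & remaining
        selected.append(SelectedVariant(
            accession=best,
            peptides=tuple(sorted(assigned, key=row_order.__getitem__)),
            round=round_no,
        ))
        candidates.remove(best)
        survivors = []
        for v in candidates:
            vset = inc.peptide_set(v) & remaining
            if vset <= assigned:
                pruned.append((v, f"subsumed_by:{best}"))
            else:
                survivors.append(v)
        candidates = survivors
        remaining = remaining - assigned

    result = InferenceResult(selected=selected, pruned=pruned,
                             unassigned=unassigned)
    _annotate(result, inc)
    return result


def _distinguishing_peptides(result: InferenceResult, inc: IncidenceMatrix,
                             accession: str) -> list[str]:
    """Assigned peptides of *accession* contained in no other database entry.

    These are the variant-specific peptides among the assigned set — the
    evidence that distinguishes this entry from every alternative
    explanation in the restricted database.
    """
    other_members: set[str] = set()
    for a in inc.variants:
        if a != accession:
            other_members |= inc.peptide_set(a)
    return [p for p in result.assigned(accession) if p not in other_members]


def _annotate(result: InferenceResult, inc: IncidenceMatrix,
              policy: PruningPolicy | None = None) -> None:
    """Fill evidence classes and (when sequences are known) coverage."""
    for s in result.selected:
        distinguishing = _distinguishing_peptides(result, inc, s.accession)
        psms = [p for pep in distinguishing for p in inc.psm_support.get(pep, [])]
        if policy is not None:
            psms = [p for p in psms if policy.acceptable(p)]
        result.evidence_class[s.accession] = (
            "single-unique-peptide" if len(psms) == 1 else "multi-peptide")
        if s.accession in inc.sequences:
            result.coverage[s.accession] = sequence_coverage(
                inc.sequences[s.accession], s.peptides)


def exact_min_cover(inc: IncidenceMatrix,
                    max_variants: int = 20) -> list[frozenset]:
    """All minimum-cardinality variant subsets covering every explainable
    peptide, by exhaustive subset enumeration.

    Intended as a validation oracle for the parsimony objective on small
    instances; refuses matrices with more than *max_variants* columns.
    """
    if len(inc.variants) > max_variants:
        raise InferenceError(
            f"{len(inc.variants)} variants exceed the exhaustive-search limit "
            f"of {max_variants}; use greedy_parsimony for large instances")
    universe = frozenset(p for i, p in enumerate(inc.peptides)
                         if inc.membership[i].any())
    sets = {v: inc.peptide_set(v) for v in inc.variants}
    for size in range(len(inc.variants) + 1):
        covers = [frozenset(combo)
                  for combo in itertools.combinations(inc.variants, size)
                  if frozenset().union(*(sets[v] for v in combo)) >= universe
                  or (size == 0 and not universe)]
        if covers:
            return covers
    return []


def prune_single_evidence(result: InferenceResult, inc: IncidenceMatrix,
                          policy: PruningPolicy | None = None) -> InferenceResult:
    """Remove selected entries whose distinguishing evidence is doubtful.

    An entry's distinguishing evidence is the set of PSMs supporting its
    variant-specific peptides — assigned peptides that occur in no other
    database entry, i.e. the only evidence separating this entry from the
    alternative explanations.  An entry with distinguishing peptides is
    removed when fewer than ``min_unique_psms`` of those PSMs are acceptable
    under the policy; its peptides return to the pool and greedy assignment
    is re-run over the remaining candidates, so no peptide another database
    variant can explain is ever orphaned.  An entry selected purely on
    shared peptides (no variant-specific claim) is never removed here.
    Entries retained on exactly one acceptable PSM are flagged
    ``single-unique-peptide`` for manual review.
    """
    policy = policy or PruningPolicy()
    excluded: list[tuple[str, str]] = []
    current = result
    while True:
        violations = []
        for s in current.selected:
            distinguishing = _distinguishing_peptides(current, inc, s.accession)
            if not distinguishing:
                # selected purely on peptides shared with other candidates
                # (e.g. the representative of an indistinguishable group):
                # there is no variant-specific claim to doubt
                continue
            psms = [p for pep in distinguishing
                    for p in inc.psm_support.get(pep, [])]
            acceptable = [p for p in psms if policy.acceptable(p)]
            if len(acceptable) < policy.min_unique_psms:
                if len(psms) == 1 and not acceptable:
                    reason = "single_doubtful_evidence"
                else:
                    reason = "below_unique_psm_threshold"
                violations.append((len(acceptable), s.accession, reason))
        if not violations:
            break
        violations.sort()
        _, accession, reason = violations[0]
        excluded.append((accession, reason))
        keep = [v for v in inc.variants
                if v not in {a for a, _ in excluded}]
        current = greedy_parsimony(inc.restrict(keep))
    final = InferenceResult(
        selected=current.selected,
        pruned=list(current.pruned) + excluded,
        unassigned=current.unassigned,
    )
    _annotate(final, inc, policy)
    return final


SCENARIO_LABELS = ("distinct", "differentiable", "indistinguishable",
                   "subset", "subsumable", "shared-only", "random-assignment")


@dataclass(frozen=True)
class ScenarioLabel:
    """A labelled group of accessions describing their peptide-sharing
    relationship."""

    accessions: tuple[str, ...]
    label: str


def _components(sets: dict[str, frozenset]) -> list[list[str]]:
    """Connected components of the shares-a-peptide graph."""
    accs = [a for a, s in sets.items() if s]
    seen: set[str] = set()
    comps = []
    for a in accs:
        if a in seen:
            continue
        comp, stack = [], [a]
        seen.add(a)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in accs:
                if y not in seen and sets[x] & sets[y]:
                    seen.add(y)
                    stack.append(y)
        comps.append(sorted(comp))
    return comps


def classify_scenarios(inc: IncidenceMatrix) -> list[ScenarioLabel]:
    """Label the peptide-grouping scenarios present in an incidence matrix.

    Pairwise labels (over variants sharing at least one peptide universe):
    ``distinct`` (disjoint peptide sets), ``indistinguishable`` (equal sets),
    ``subset`` (proper containment), ``differentiable`` (overlap with a
    unique peptide on each side).  Group labels over connected components of
    the sharing graph: ``subsumable`` (some member's set is covered by the
    union of the others without equalling any), ``shared-only`` (no member
    retains a unique peptide), and ``random-assignment`` — the pattern where
    a single member's peptide set contains the union of all the others', so
    one entry suffices to explain the whole group's evidence.
    """
    sets = {v: inc.peptide_set(v) for v in inc.variants}
    nonempty = [v for v in inc.variants if sets[v]]
    labels: list[ScenarioLabel] = []
    for a, b in itertools.combinations(nonempty, 2):
        sa, sb = sets[a], sets[b]
        if sa == sb:
            label = "indistinguishable"
        elif not (sa & sb):
            label = "distinct"
        elif sa < sb or sb < sa:
            label = "subset"
        else:
            label = "differentiable"
        labels.append(ScenarioLabel((a, b), label))

    for comp in _components(sets):
        if len(comp) < 2:
            continue
        group = tuple(comp)
        union_all = frozenset().union(*(sets[v] for v in comp))
        for v in comp:
            union_others = frozenset().union(
                *(sets[w] for w in comp if w != v))
            if (sets[v] >= union_others
                    and any(sets[w] != sets[v] for w in comp if w != v)):
                labels.append(ScenarioLabel(group, "random-assignment"))
                break
        for v in comp:
            union_others = frozenset().union(
                *(sets[w] for w in comp if w != v))
            if (sets[v] <= union_others
                    and all(sets[w] != sets[v] for w in comp if w != v)):
                labels.append(ScenarioLabel(group, "subsumable"))
                break
        counts = {p: sum(1 for v in inc.variants if p in sets[v])
                  for p in union_all}
        if all(counts[p] > 1 for p in union_all) and union_all:
            labels.append(ScenarioLabel(group, "shared-only"))
    return labels
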