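"""Greedy parsimony, the exhaustive minimum-cover oracle, evidence pruning,
scenario classification and coverage."""

import numpy as np
import pytest

from varinfer.inference import (InferenceError, PruningPolicy, ScenarioLabel,
                                classify_scenarios, exact_min_cover,
                                greedy_parsimony, prune_single_evidence,
                                sequence_coverage)
from varinfer.psm import PSM, IncidenceMatrix
from varinfer.simulate import random_incidence_matrix
from varinfer.variantdb import VariantEntry


def make_incidence(sets: dict[str, set[str]],
                   support: dict[str, list[PSM]] | None = None):
    """Incidence matrix from accession -> peptide-set mapping."""
    peptides = sorted(set().union(*sets.values())) if sets else []
    variants = list(sets)
    membership = np.array([[p in sets[v] for v in variants]
                           for p in peptides], dtype=bool)
    if support is None:
        support = {p: [PSM("S1", "GK", 1, 100.0)] for p in peptides}
    return IncidenceMatrix(peptides, variants, membership, support)


def test_one_entry_explains_all_peptides(worked_example_incidence):
    result = greedy_parsimony(worked_example_incidence)
    assert result.accessions == ["A"]
    assert len(result.selected[0].peptides) == 5
    assert sorted(result.pruned) == [("B", "subsumed_by:A"),
                                     ("C", "subsumed_by:A")]
    assert result.unassigned == []


def test_empty_incidence_yields_empty_result():
    inc = make_incidence({})
    result = greedy_parsimony(inc)
    assert result.selected == [] and result.pruned == []
    assert exact_min_cover(inc) == [frozenset()]


def test_overlapping_chain_selects_exact_minimum():
    inc = make_incidence({"A": {"p1", "p2"}, "B": {"p2", "p3"},
                          "C": {"p3", "p4"}})
    result = greedy_parsimony(inc)
    assert result.accessions == ["A", "C"]
    covers = exact_min_cover(inc)
    assert len(result.selected) == len(covers[0]) == 2
    assert frozenset(result.accessions) in covers
    sets = [set(s.peptides) for s in result.selected]
    assert sets[0] & sets[1] == set()
    assert sets[0] | sets[1] == {"p1", "p2", "p3", "p4"}


def test_exact_min_cover_fig_structure(worked_example_incidence):
    covers = exact_min_cover(worked_example_incidence)
    assert covers == [frozenset({"A"})]


def test_exact_min_cover_disjoint_singletons():
    inc = make_incidence({"A": {"p1"}, "B": {"p2"}, "C": {"p3"}})
    covers = exact_min_cover(inc)
    assert covers == [frozenset({"A", "B", "C"})]


def test_exact_min_cover_refuses_large_instances():
    inc = make_incidence({f"V{i}": {"p"} for i in range(25)})
    with pytest.raises(InferenceError, match="exceed"):
        exact_min_cover(inc)


def test_greedy_against_exhaustive_oracle(rng):
    """Greedy always covers every explainable peptide with disjoint
    assignments and never reports fewer entries than the exhaustive
    minimum."""
    for _ in range(100):
        inc = random_incidence_matrix(rng)
        result = greedy_parsimony(inc)
        explainable = {p for i, p in enumerate(inc.peptides)
                       if inc.membership[i].any()}
        assigned = [set(s.peptides) for s in result.selected]
        union = set().union(*assigned) if assigned else set()
        assert union == explainable
        for i, a in enumerate(assigned):
            for b in assigned[i + 1:]:
                assert not (a & b)
        covers = exact_min_cover(inc, max_variants=10)
        minimum = len(covers[0]) if covers else 0
        assert len(result.selected) >= minimum
        assert len(result.selected) <= max(len(explainable), minimum)


def test_greedy_can_overshoot_when_a_decoy_masks_forced_entries():
    """Known limitation of greedy set cover: a non-essential entry matching
    the most peptides can be selected first even though the entries forced
    by unique peptides already cover everything."""
    inc = make_incidence({
        "A": {"uA", "s1", "s2", "s3"},
        "B": {"uB", "s4", "s5"},
        "D": {"s1", "s2", "s3", "s4", "s5"},
    })
    result = greedy_parsimony(inc)
    assert result.accessions == ["D", "A", "B"]
    assert exact_min_cover(inc) == [frozenset({"A", "B"})]


def test_determinism_of_greedy_output(rng):
    inc = random_incidence_matrix(rng)
    first = greedy_parsimony(inc)
    second = greedy_parsimony(inc)
    assert first.selected == second.selected
    assert first.pruned == second.pruned


def test_tie_break_prefers_higher_summed_score():
    support = {"p1": [PSM("S1", "GK", 1, 10.0)],
               "p2": [PSM("S1", "GK", 1, 500.0)]}
    inc = make_incidence({"A": {"p1"}, "B": {"p2"}}, support)
    result = greedy_parsimony(inc)
    assert result.accessions[0] == "B"


def test_tie_break_falls_back_to_accession():
    inc = make_incidence({"Z": {"p1", "p2"}, "A": {"p1", "p2"}})
    result = greedy_parsimony(inc)
    assert result.accessions == ["A"]
    assert result.pruned == [("Z", "subsumed_by:A")]


def _planted_decoy():
    """True variant T explains s1..s3; decoy D shares s1..s3 and adds a
    unique peptide u supported by one tier-2 PSM only."""
    support = {
        "s1": [PSM("S1", "GK", 1, 900.0)],
        "s2": [PSM("S1", "GK", 1, 800.0)],
        "s3": [PSM("S1", "GK", 1, 700.0)],
        "u": [PSM("S1", "GK", 2, 50.0)],
    }
    inc = make_incidence({"T": {"s1", "s2", "s3"},
                          "D": {"s1", "s2", "s3", "u"}}, support)
    return inc


def test_prune_removes_single_tier2_evidence_variant():
    inc = _planted_decoy()
    raw = greedy_parsimony(inc)
    assert raw.accessions == ["D"]  # decoy wins on peptide count
    pruned = prune_single_evidence(raw, inc, PruningPolicy())
    assert pruned.accessions == ["T"]
    assert ("D", "single_doubtful_evidence") in pruned.pruned
    assert set(pruned.selected[0].peptides) == {"s1", "s2", "s3"}


def test_variant_with_two_acceptable_unique_psms_is_retained():
    support = {
        "s1": [PSM("S1", "GK", 1, 900.0)],
        "u1": [PSM("S1", "GK", 1, 500.0)],
        "u2": [PSM("S1", "GK", 1, 400.0)],
    }
    inc = make_incidence({"T": {"s1", "u1", "u2"}}, support)
    result = prune_single_evidence(greedy_parsimony(inc), inc,
                                   PruningPolicy())
    assert result.accessions == ["T"]
    assert result.evidence_class["T"] == "multi-peptide"


def test_manual_mode_retains_and_flags_single_unique_evidence():
    support = {
        "s1": [PSM("S1", "GK", 1, 900.0)],
        "u": [PSM("S1", "GK", 1, 500.0)],
    }
    inc = make_incidence({"T": {"s1"}, "V": {"s1", "u"}}, support)
    manual = prune_single_evidence(greedy_parsimony(inc), inc,
                                   PruningPolicy(min_unique_psms=1))
    assert manual.accessions == ["V"]
    assert manual.evidence_class["V"] == "single-unique-peptide"
    default = prune_single_evidence(greedy_parsimony(inc), inc,
                                    PruningPolicy())
    assert default.accessions == ["T"]
    assert ("V", "below_unique_psm_threshold") in default.pruned


def test_score_floor_marks_low_scoring_unique_evidence_doubtful():
    support = {
        "s1": [PSM("S1", "GK", 1, 900.0)],
        "u": [PSM("S1", "GK", 1, 5.0)],
    }
    inc = make_incidence({"T": {"s1"}, "V": {"s1", "u"}}, support)
    result = prune_single_evidence(
        greedy_parsimony(inc), inc,
        PruningPolicy(min_unique_psms=1, score_floor=10.0))
    assert result.accessions == ["T"]
    assert ("V", "single_doubtful_evidence") in result.pruned


def test_pruning_never_orphans_explainable_peptides(rng):
    """After policy removals, every peptide a surviving database variant
    could explain is still assigned (only peptides whose sole explaining
    entries were removed may become unassigned)."""
    for _ in range(50):
        inc = random_incidence_matrix(rng)
        raw = greedy_parsimony(inc)
        result = prune_single_evidence(raw, inc, PruningPolicy())
        removed = {acc for acc, reason in result.pruned
                   if not reason.startswith("subsumed_by:")}
        surviving = [v for v in inc.variants if v not in removed]
        cols = [inc.variants.index(v) for v in surviving]
        explainable = {p for i, p in enumerate(inc.peptides)
                       if inc.membership[i, cols].any()}
        assigned = set().union(*(set(s.peptides) for s in result.selected)) \
            if result.selected else set()
        assert assigned == explainable


def test_tier2_only_decoys_are_neutral_after_filtering(worked_example_db,
                                                       worked_example_psms):
    from varinfer.psm import build_incidence, filter_pass_two
    decoys = [PSM("28", "WK", 2, 5.0), PSM("28", "YK", 2, 5.0)]
    base, _ = build_incidence(filter_pass_two(worked_example_psms),
                              worked_example_db)
    spiked, _ = build_incidence(
        filter_pass_two(worked_example_psms + decoys), worked_example_db)
    assert greedy_parsimony(base).selected == greedy_parsimony(spiked).selected


def test_scenario_labels_pairwise():
    assert classify_scenarios(make_incidence({"A": {"p1"}, "B": {"p2"}})) == \
        [ScenarioLabel(("A", "B"), "distinct")]
    labels = classify_scenarios(
        make_incidence({"A": {"p1", "p2"}, "B": {"p1", "p2"}}))
    assert ScenarioLabel(("A", "B"), "indistinguishable") in labels
    labels = classify_scenarios(
        make_incidence({"A": {"p1", "p2"}, "B": {"p2", "p3"}}))
    assert ScenarioLabel(("A", "B"), "differentiable") in labels


def test_scenario_random_assignment_flag(worked_example_incidence):
    labels = classify_scenarios(worked_example_incidence)
    assert ScenarioLabel(("A", "B", "C"), "random-assignment") in labels


def test_scenario_shared_only_group():
    labels = classify_scenarios(
        make_incidence({"A": {"p1", "p2"}, "B": {"p2", "p3"},
                        "C": {"p3", "p1"}}))
    assert ScenarioLabel(("A", "B", "C"), "shared-only") in labels


def test_sequence_coverage_values():
    entry = VariantEntry("X", "", "A" * 108 + "CDEFGHIKLMNP")
    assert sequence_coverage(entry, ["CDEFGHIKLMNP"]) == pytest.approx(10.0)
    assert sequence_coverage(entry, []) == 0.0
    assert sequence_coverage(VariantEntry("Y", "", "MKGGGR"),
                             ["MK", "GGGR"]) == 100.0
    # overlapping peptides count residues once
    assert sequence_coverage("AAAABBBB".replace("B", "C"),
                             ["AAAA", "AAAACC"]) == pytest.approx(75.0)
    with pytest.raises(InferenceError, match="not locatable"):
        sequence_coverage(entry, ["WWWW"])
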