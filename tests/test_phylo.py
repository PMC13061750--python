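"""Tree annotation: state attachment, Fitch parsimony, branch changes,
hotspot clades."""

import random

import dendropy
import pytest

from conftest import oracle_parsimony_score
from mitorder.events import RearrangementEvent, apply_event
from mitorder.orders import PANGO, GeneOrderClass
from mitorder.phylo import (
    EXCLUDED,
    ancestral_states,
    annotate_branch_changes,
    attach_states,
    find_hotspots,
)


def make_classes(*orders):
    return {
        f"GO {k+1}": GeneOrderClass(f"GO {k+1}", o, [f"m{k}"])
        for k, o in enumerate(orders)
    }


NAD1_FLIP = apply_event(PANGO, RearrangementEvent("I", ("nad1",)))
COX2_MOVE = apply_event(
    PANGO, RearrangementEvent("T", ("cox2",), destination="cytb")
)
NAD6_MOVE = apply_event(
    PANGO, RearrangementEvent("T", ("nad6",), destination="cox3")
)


class TestAttachStates:
    def test_four_tips_all_assigned(self):
        at = attach_states(
            "((a,b),(c,d));",
            {"a": "GO 1", "b": "GO 1", "c": "GO 2", "d": "GO 2"},
            make_classes(PANGO, NAD1_FLIP),
        )
        assert at.tip_states == {
            "a": "GO 1", "b": "GO 1", "c": "GO 2", "d": "GO 2"
        }
        assert at.excluded_tips() == []

    def test_unassigned_tip_flagged_excluded(self):
        at = attach_states(
            "((a,b),(c,d));",
            {"a": "GO 1", "b": "GO 1", "c": "GO 1"},
            make_classes(PANGO),
        )
        assert at.tip_states["d"] == EXCLUDED
        assert at.excluded_tips() == ["d"]

    def test_label_normalization_spaces_underscores_accessions(self):
        at = attach_states(
            "((Gammarus_lacustris,b),(c,d));",
            {
                "Gammarus lacustris|MN123": "GO 1",
                "b": "GO 1", "c": "GO 1", "d": "GO 1",
            },
            make_classes(PANGO),
        )
        assert at.tip_states["Gammarus_lacustris"] == "GO 1"

    def test_orphan_assignment_is_an_error(self):
        with pytest.raises(ValueError, match="absent from the tree"):
            attach_states(
                "((a,b),(c,d));",
                {"a": "GO 1", "nope": "GO 1"},
                make_classes(PANGO),
            )

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate tip|invalid newick"):
            attach_states(
                "((a,a),(c,d));", {"a": "GO 1"}, make_classes(PANGO)
            )


class TestAncestralStates:
    def test_uniform_tips_resolve_everywhere(self):
        at = attach_states(
            "((a,b),(c,d));", {t: "GO 1" for t in "abcd"}, make_classes(PANGO)
        )
        ancestral_states(at)
        assert set(at.resolved.values()) == {"GO 1"}
        assert at.parsimony_score == 0

    def test_no_assigned_tips_is_an_error(self):
        at = attach_states("((a,b),(c,d));", {}, {})
        with pytest.raises(ValueError, match="no assigned tips"):
            ancestral_states(at)

    def test_excluded_tip_does_not_perturb_reconstruction(self):
        at = attach_states(
            "((a,b),(c,d));",
            {"a": "GO 1", "b": "GO 1", "c": "GO 1"},
            make_classes(PANGO),
        )
        ancestral_states(at)
        root = at.node_id(at.tree.seed_node)
        assert at.resolved[root] == "GO 1"

    @pytest.mark.parametrize("seed", range(8))
    def test_fitch_score_matches_bruteforce_on_small_trees(self, seed):
        rng = random.Random(seed)
        n_tips = rng.randint(4, 8)
        taxa = [f"t{k}" for k in range(n_tips)]
        # random binary topology by sequential attachment
        newick = taxa[0]
        for t in taxa[1:]:
            newick = f"({newick},{t})" if rng.random() < 0.5 else f"({t},{newick})"
        states = [f"GO {k+1}" for k in range(rng.randint(2, 4))]
        assignment = {t: rng.choice(states) for t in taxa}
        classes = {
            s: GeneOrderClass(s, PANGO, [s]) for s in states
        }
        at = attach_states(newick + ";", assignment, classes)
        ancestral_states(at)
        tree = dendropy.Tree.get(data=newick + ";", schema="newick")
        tree.is_rooted = True
        want = oracle_parsimony_score(tree, assignment)
        assert at.parsimony_score == want

    def test_branch_change_count_equals_parsimony_score(self):
        rng = random.Random(3)
        taxa = [f"t{k}" for k in range(7)]
        newick = f"(((({taxa[0]},{taxa[1]}),{taxa[2]}),({taxa[3]},{taxa[4]})),({taxa[5]},{taxa[6]}));"
        orders = [PANGO, NAD1_FLIP, COX2_MOVE]
        classes = make_classes(*orders)
        assignment = {t: f"GO {rng.randint(1, 3)}" for t in taxa}
        at = attach_states(newick, assignment, classes)
        ancestral_states(at)
        annotate_branch_changes(at, all_minimal=False)
        if all(len(s) == 1 for s in at.node_states.values() if s):
            assert len(at.branch_changes) == at.parsimony_score


class TestBranchChanges:
    def test_identical_states_no_annotation(self):
        at = attach_states(
            "((a,b),(c,d));", {t: "GO 1" for t in "abcd"}, make_classes(PANGO)
        )
        ancestral_states(at)
        annotate_branch_changes(at)
        assert at.branch_changes == {}

    def test_planted_single_inversion_branch_annotated(self):
        at = attach_states(
            "((a,b),(c,d));",
            {"a": "GO 1", "b": "GO 1", "c": "GO 1", "d": "GO 2"},
            make_classes(PANGO, NAD1_FLIP),
        )
        ancestral_states(at)
        annotate_branch_changes(at)
        assert set(at.branch_changes) == {"d"}
        bc = at.branch_changes["d"]
        assert bc.steps == 1
        assert bc.preferred_scenario == "I[nad1]"
        assert bc.genes_moved == ("nad1",)

    def test_convergent_derived_orders_annotated_on_both_branches(self):
        # the same derived class at two distant tips: two independent
        # change branches (homoplasy), not one deep change
        at = attach_states(
            "((a,b),((c,d),(e,f)));",
            {
                "a": "GO 1", "b": "GO 2", "c": "GO 1",
                "d": "GO 1", "e": "GO 2", "f": "GO 1",
            },
            make_classes(PANGO, NAD1_FLIP),
        )
        ancestral_states(at)
        annotate_branch_changes(at)
        assert set(at.branch_changes) == {"b", "e"}
        assert (
            at.branch_changes["b"].target_class
            == at.branch_changes["e"].target_class
            == "GO 2"
        )


class TestHotspots:
    def test_uniform_tree_has_no_hotspots(self):
        at = attach_states(
            "((a,b),(c,d));", {t: "GO 1" for t in "abcd"}, make_classes(PANGO)
        )
        ancestral_states(at)
        assert find_hotspots(at) == []

    def test_planted_two_derived_clade_is_found_exactly(self):
        at = attach_states(
            "((a,b),((c,d),(e,f)));",
            {
                "a": "GO 1", "b": "GO 1", "c": "GO 2",
                "d": "GO 3", "e": "GO 1", "f": "GO 1",
            },
            make_classes(PANGO, NAD1_FLIP, COX2_MOVE),
        )
        ancestral_states(at)
        hits = find_hotspots(at)
        assert len(hits) == 1
        assert set(hits[0].tips) == {"c", "d"}
        assert hits[0].unique_GOs == frozenset({"GO 2", "GO 3"})
        assert hits[0].ancestral_GO == "GO 1"

    def test_single_derived_class_is_not_a_hotspot(self):
        at = attach_states(
            "((a,b),((c,d),(e,f)));",
            {
                "a": "GO 1", "b": "GO 1", "c": "GO 2",
                "d": "GO 2", "e": "GO 1", "f": "GO 1",
            },
            make_classes(PANGO, NAD1_FLIP),
        )
        ancestral_states(at)
        assert find_hotspots(at) == []

    def test_maximality_no_hotspot_contains_another(self):
        at = attach_states(
            "(((a,b),(c,d)),((e,f),(g,h)));",
            {
                "a": "GO 2", "b": "GO 3", "c": "GO 4", "d": "GO 2",
                "e": "GO 1", "f": "GO 1", "g": "GO 1", "h": "GO 1",
            },
            make_classes(PANGO, NAD1_FLIP, COX2_MOVE, NAD6_MOVE),
        )
        ancestral_states(at)
        hits = find_hotspots(at)
        tip_sets = [set(h.tips) for h in hits]
        for i, s in enumerate(tip_sets):
            for j, t in enumerate(tip_sets):
                if i != j:
                    assert not s <= t
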