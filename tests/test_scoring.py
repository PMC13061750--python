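"""Repositioned-gene scoring and simple/complex classification."""

import random

import pytest

from conftest import oracle_min_deletion_sets, plant_events, random_order
from mitorder.events import RearrangementEvent, apply_event
from mitorder.orders import PANGO, GeneOrderClass, SignedGeneOrder
from mitorder.scenarios import infer_scenarios, ScenarioInference
from mitorder.scoring import (
    aggregate_reposition_counts,
    classify_transition,
    reposition_score,
)


class TestRepositionScore:
    def test_reference_scores_zero_with_one_block(self, pango):
        s = reposition_score(pango)
        assert s.count == 0 and s.flagged == ()
        assert s.blocks == (pango.labels(),)

    def test_single_transposed_gene_scores_one(self, pango):
        b = apply_event(
            pango, RearrangementEvent("T", ("cox2",), destination="cytb")
        )
        s = reposition_score(b)
        assert s.count == 1 and s.flagged == ("cox2",)

    def test_strand_flip_in_place_scores_that_gene(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        s = reposition_score(b)
        assert s.count == 1 and s.flagged == ("nad1",)

    def test_inverted_segment_scores_at_most_its_length(self, pango):
        for L, start in [(2, 1), (3, 5), (4, 8)]:
            seg = pango.labels()[start : start + L]
            b = apply_event(pango, RearrangementEvent("I", seg))
            assert reposition_score(b).count <= L

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_minimum_deletion_oracle(self, seed):
        order = random_order(random.Random(seed))
        k, sets = oracle_min_deletion_sets(order, PANGO)
        s = reposition_score(order)
        assert s.count == k
        assert s.flagged == sets[0]  # lexicographically smallest tie-break

    def test_count_zero_iff_equal_to_reference(self, pango):
        rng = random.Random(100)
        for _ in range(10):
            order = random_order(rng)
            s = reposition_score(order)
            assert (s.count == 0) == (order == pango)

    def test_deleting_flagged_genes_reconciles_sequences(self, pango):
        rng = random.Random(7)
        for _ in range(10):
            order = random_order(rng)
            s = reposition_score(order)
            drop = set(s.flagged)
            left = [(g.label, g.strand) for g in order if g.label not in drop]
            right = [(g.label, g.strand) for g in pango if g.label not in drop]
            assert left == right


class TestAggregation:
    def _cls(self, cid, order, members):
        return GeneOrderClass(cid, order, list(members))

    def test_empty_input_gives_all_zero_table(self):
        df = aggregate_reposition_counts([])
        assert len(df) == 13 and (df["count"] == 0).all()

    def test_per_go_counts_each_class_once(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        scored = [
            (self._cls("GO 1", pango, ["s1", "s2"]), reposition_score(pango)),
            (self._cls("GO 2", b, ["s3", "s4", "s5"]), reposition_score(b)),
        ]
        df = aggregate_reposition_counts(scored, unit="per_GO")
        assert int(df.loc[df.gene == "nad1", "count"].sum()) == 1

    def test_per_species_counts_members(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        scored = [
            (self._cls("GO 2", b, ["s3", "s4", "s5"]), reposition_score(b)),
        ]
        df = aggregate_reposition_counts(scored, unit="per_species")
        assert int(df.loc[df.gene == "nad1", "count"].sum()) == 3

    def test_group_sums_match_total_and_missing_species_error(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        c = apply_event(
            pango, RearrangementEvent("T", ("cox2",), destination="cytb")
        )
        scored = [
            (self._cls("GO 2", b, ["s1", "s2"]), reposition_score(b)),
            (self._cls("GO 3", c, ["s3"]), reposition_score(c)),
        ]
        grouping = {"s1": "baikal", "s2": "other", "s3": "other"}
        df = aggregate_reposition_counts(scored, grouping, unit="per_species")
        total = aggregate_reposition_counts(scored, None, unit="per_species")
        merged = df.groupby("gene")["count"].sum()
        for gene in merged.index:
            assert merged[gene] == int(
                total.loc[total.gene == gene, "count"].sum()
            )
        with pytest.raises(KeyError, match="s4"):
            aggregate_reposition_counts(
                [(self._cls("GO 4", b, ["s4"]), reposition_score(b))],
                grouping,
            )

    def test_planted_flag_counts_recovered(self, pango):
        # nad1 flagged in exactly 3 planted classes
        variants = []
        for dest in ("cox3", "atp6", "cox2"):
            variants.append(
                apply_event(
                    pango, RearrangementEvent("T", ("nad1",), destination=dest)
                )
            )
        scored = [
            (self._cls(f"GO {k+2}", v, [f"s{k}"]), reposition_score(v))
            for k, v in enumerate(variants)
        ]
        df = aggregate_reposition_counts(scored, unit="per_GO")
        assert int(df.loc[df.gene == "nad1", "count"].sum()) == 3


class TestClassification:
    def test_single_transposition_is_simple(self, pango):
        b = apply_event(
            pango, RearrangementEvent("T", ("cox2",), destination="cytb")
        )
        v = classify_transition(infer_scenarios(pango, b))
        assert v.verdict == "simple" and v.triggered == frozenset()

    def test_two_transpositions_are_complex_via_multi_step(self, pango):
        for seed in range(5):
            _, b = plant_events(pango, ["T", "T"], seed=seed)
            inf = infer_scenarios(pango, b)
            if inf.min_steps == 2:
                v = classify_transition(inf)
                assert v.verdict == "complex"
                assert "multi_step" in v.triggered
                return
        raise AssertionError("no seed produced a genuine 2-step pair")

    def test_tdrl_bearing_single_step_is_complex(self, pango):
        segment = pango.labels()
        pattern = (1, 2, 1, 2, 1, 2, 1, 1, 1, 1, 1, 1, 1)
        b = apply_event(
            pango, RearrangementEvent("TDRL", segment, loss_pattern=pattern)
        )
        inf = infer_scenarios(pango, b)
        assert inf.min_steps == 1
        v = classify_transition(inf)
        assert v.verdict == "complex" and "has_tdrl" in v.triggered

    def test_bound_exceeded_is_complex_with_note(self, pango):
        inf = ScenarioInference(
            source=pango, target=pango, max_steps=1, exceeded_bound=True
        )
        v = classify_transition(inf)
        assert v.verdict == "complex"
        assert v.triggered == frozenset({"multi_step"})
        assert "exceeds" in v.note

    def test_identity_transition_is_simple(self, pango):
        v = classify_transition(infer_scenarios(pango, pango))
        assert v.verdict == "simple"
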