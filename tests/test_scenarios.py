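"""Scenario inference, common intervals and TDRL polarity."""

import random

import pytest

from conftest import (
    oracle_common_intervals,
    oracle_tdrl_results,
    plant_events,
    random_order,
)
from mitorder.events import RearrangementEvent, apply_event
from mitorder.orders import PANGO, SignedGeneOrder, orders_equal
from mitorder.scenarios import (
    ancestral_direction,
    common_intervals,
    infer_scenarios,
    rearrangement_distance,
    tdrl_reachable_one_step,
)


class TestCommonIntervals:
    def test_self_comparison_counts_all_windows(self, pango):
        # frozen from the exhaustive-subset oracle: windows of length
        # 2..12 of a 13-gene linear order
        assert oracle_common_intervals(pango, pango) == common_intervals(
            pango, pango
        ).intervals
        assert common_intervals(pango, pango).nsci == 77

    def test_adjacent_swap_example_matches_oracle(self, pango):
        # swapping the first two genes keeps every interval containing
        # both or neither; frozen value from the oracle
        swapped = SignedGeneOrder(
            (pango.genes[1], pango.genes[0]) + pango.genes[2:]
        )
        want = oracle_common_intervals(pango, swapped)
        got = common_intervals(pango, swapped)
        assert got.intervals == want
        assert got.nsci == len(want) == 56

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_random_pairs(self, seed):
        rng = random.Random(seed)
        a, b = random_order(rng), random_order(rng)
        assert common_intervals(a, b).intervals == oracle_common_intervals(a, b)

    def test_symmetric_and_self_maximal(self, pango):
        rng = random.Random(17)
        self_nsci = common_intervals(pango, pango).nsci
        for _ in range(5):
            b = random_order(rng)
            assert common_intervals(pango, b).nsci == common_intervals(b, pango).nsci
            assert common_intervals(pango, b).nsci <= self_nsci

    def test_signs_are_ignored(self, pango):
        flipped = SignedGeneOrder(tuple(g.flipped() if g.label == "nad4" else g
                                        for g in pango.genes))
        assert common_intervals(pango, flipped).nsci == 77


class TestInferScenarios:
    def test_identity_yields_zero_step_scenario(self, pango):
        inf = infer_scenarios(pango, pango)
        assert inf.min_steps == 0
        assert len(inf.scenarios) == 1 and inf.scenarios[0].steps == 0

    @pytest.mark.parametrize("kind", ["T", "I", "iT", "TDRL"])
    def test_single_planted_event_recovered(self, kind, pango):
        events, b = plant_events(pango, [kind], seed=hash(kind) % 1000)
        inf = infer_scenarios(pango, b)
        assert inf.min_steps == 1
        assert all(s.replays_correctly() for s in inf.scenarios)
        assert kind in {s.events[0].kind for s in inf.scenarios}

    def test_nad1_strand_flip_is_one_inversion(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        inf = infer_scenarios(pango, b)
        assert inf.min_steps == 1
        assert str(inf.preferred) == "I[nad1]"

    def test_two_step_planted_bounded_and_replayable(self, pango):
        events, b = plant_events(pango, ["T", "I"], seed=42)
        inf = infer_scenarios(pango, b)
        assert inf.min_steps is not None and inf.min_steps <= 2
        assert all(s.replays_correctly() for s in inf.scenarios)

    def test_exceeding_bound_is_flagged_not_raised(self, pango):
        rng = random.Random(123)
        # a thoroughly scrambled order is almost surely > 1 step away
        b = random_order(rng)
        inf = infer_scenarios(pango, b, max_steps=1)
        if inf.min_steps is None:
            assert inf.exceeded_bound and inf.scenarios == []
        else:
            assert inf.min_steps <= 1

    def test_distance_only_variant_agrees(self, pango):
        for seed in range(3):
            _, b = plant_events(pango, ["T", "T"], seed=seed)
            inf = infer_scenarios(pango, b)
            assert rearrangement_distance(pango, b) == inf.min_steps


class TestTdrlReachability:
    def test_strand_difference_is_immediately_false(self, pango):
        b = apply_event(pango, RearrangementEvent("I", ("nad1",)))
        ok, witness = tdrl_reachable_one_step(pango, b)
        assert not ok and witness is None

    def test_planted_whole_order_tdrl_found_with_replaying_witness(self, pango):
        segment = pango.labels()
        pattern = tuple(2 if g in ("nad5", "nad4", "cytb") else 1 for g in segment)
        b = apply_event(
            pango, RearrangementEvent("TDRL", segment, loss_pattern=pattern)
        )
        ok, witness = tdrl_reachable_one_step(pango, b)
        assert ok
        assert witness.kind == "TDRL"
        assert orders_equal(apply_event(pango, witness), b)

    def test_agreement_with_duplicate_then_delete_oracle(self, pango):
        reachable = oracle_tdrl_results(pango)
        rng = random.Random(9)
        # positives: sampled oracle results; negatives: random orders
        positives = rng.sample(sorted(reachable, key=str), 25)
        for form in positives:
            ok, w = tdrl_reachable_one_step(pango, SignedGeneOrder(form))
            assert ok and orders_equal(
                apply_event(pango, w), SignedGeneOrder(form)
            )
        for _ in range(25):
            b = random_order(rng)
            ok, _ = tdrl_reachable_one_step(pango, b)
            assert ok == (b.canonical_form in reachable)


class TestAncestralDirection:
    def test_identical_orders_uninformative(self, pango):
        assert ancestral_direction(pango, pango).direction == "uninformative"

    def test_symmetric_transposition_is_uninformative(self, pango):
        b = apply_event(
            pango, RearrangementEvent("T", ("cox2",), destination="cytb")
        )
        assert ancestral_direction(pango, b).direction == "uninformative"

    def test_interleaving_tdrl_polarizes_toward_the_source(self, pango):
        # a three-block interleave is one TDRL forward but needs >= 2
        # events backward: the forward source is supported as ancestral
        segment = pango.labels()
        pattern = (1, 2, 1, 2, 1, 2, 1, 1, 1, 1, 1, 1, 1)
        b = apply_event(
            pango, RearrangementEvent("TDRL", segment, loss_pattern=pattern)
        )
        rep = ancestral_direction(pango, b)
        assert rep.direction == "forward"
        assert rep.steps_forward == 1
        rev = ancestral_direction(b, pango)
        assert rev.direction == "reverse"
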