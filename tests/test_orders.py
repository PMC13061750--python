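"""Canonicalization, equality and deduplication of circular signed orders."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_order
from mitorder.genes import GENES
from mitorder.orders import (
    PANGO,
    SignedGene,
    SignedGeneOrder,
    canonicalize,
    dedupe_gene_orders,
    orders_equal,
)


class TestCanonicalization:
    def test_pango_anchored_at_cox1_plus(self, pango):
        assert pango.genes[0] == SignedGene("cox1", 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_rotation_and_reverse_complement(self, seed):
        order = random_order(random.Random(seed))
        for k in range(13):
            assert orders_equal(order, order.rotated(k))
            assert orders_equal(order, order.rotated(k).reverse_complement())

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed):
        order = random_order(random.Random(seed))
        assert canonicalize(canonicalize(order)) == canonicalize(order)

    def test_string_round_trip(self, pango):
        assert SignedGeneOrder.from_string(str(pango)) == pango

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        perm=st.permutations(list(GENES)),
        strands=st.lists(
            st.sampled_from([1, -1]), min_size=13, max_size=13
        ),
        rot=st.integers(min_value=0, max_value=12),
        flip=st.booleans(),
    )
    def test_any_presentation_of_a_circle_canonicalizes_identically(
        self, perm, strands, rot, flip
    ):
        order = SignedGeneOrder(
            tuple(SignedGene(l, s) for l, s in zip(perm, strands))
        )
        variant = order.rotated(rot)
        if flip:
            variant = variant.reverse_complement()
        assert variant == order
        assert str(SignedGeneOrder.from_string(str(variant))) == str(order)

    def test_rejects_missing_and_duplicated_genes(self):
        genes = list(PANGO.genes)
        with pytest.raises(ValueError, match="missing"):
            SignedGeneOrder(tuple(genes[:-1]))
        with pytest.raises(ValueError, match="duplicated"):
            SignedGeneOrder(tuple(genes[:-1] + [genes[0]]))


class TestEquality:
    def test_rotated_pango_equal(self, pango):
        assert orders_equal(pango, pango.rotated(5))

    def test_strand_flip_distinguishes(self, pango):
        flipped = SignedGeneOrder(
            tuple(
                g.flipped() if g.label == "nad1" else g for g in pango.genes
            )
        )
        assert not orders_equal(pango, flipped)

    def test_equivalence_relation_on_random_sample(self):
        rng = random.Random(99)
        sample = [random_order(rng) for _ in range(8)]
        variants = [o.rotated(rng.randrange(13)) for o in sample]
        for o, v in zip(sample, variants):
            assert orders_equal(o, o)            # reflexive
            assert orders_equal(o, v) == orders_equal(v, o)  # symmetric
        # transitive: canonical forms are total representatives
        for o, v in zip(sample, variants):
            w = v.reverse_complement()
            if orders_equal(o, v) and orders_equal(v, w):
                assert orders_equal(o, w)


class TestDedupe:
    def test_all_identical_gives_one_class(self, pango):
        pairs = [(f"sp{i}", pango.rotated(i)) for i in range(5)]
        classes, assignment = dedupe_gene_orders(pairs)
        assert len(classes) == 1
        assert classes[0].class_id == "GO 1"
        assert sorted(classes[0].members) == [f"sp{i}" for i in range(5)]
        assert set(assignment.values()) == {"GO 1"}

    def test_pango_class_is_always_go1(self, pango):
        other = SignedGeneOrder(
            tuple(g.flipped() if g.label == "nad1" else g for g in pango.genes)
        )
        classes, _ = dedupe_gene_orders(
            [("a", other), ("b", pango), ("c", other)]
        )
        ids = {str(c.representative): c.class_id for c in classes}
        assert ids[str(pango)] == "GO 1"
        assert len(classes) == 2

    def test_matches_bruteforce_pairwise_grouping(self):
        rng = random.Random(4)
        base = [random_order(rng) for _ in range(6)]
        orders = [(f"sp{i:02d}", rng.choice(base).rotated(rng.randrange(13)))
                  for i in range(20)]
        classes, assignment = dedupe_gene_orders(orders)

        # brute force: pairwise comparison into groups
        groups: list[list[str]] = []
        reps: list[SignedGeneOrder] = []
        for sp, o in orders:
            for g, r in zip(groups, reps):
                if orders_equal(o, r):
                    g.append(sp)
                    break
            else:
                groups.append([sp])
                reps.append(o)
        assert len(classes) == len(groups)
        got = {frozenset(c.members) for c in classes}
        want = {frozenset(g) for g in groups}
        assert got == want

    def test_empty_input(self):
        classes, assignment = dedupe_gene_orders([])
        assert classes == [] and assignment == {}

    def test_duplicate_species_rejected(self, pango):
        with pytest.raises(ValueError, match="duplicate species"):
            dedupe_gene_orders([("sp1", pango), ("sp1", pango)])


def test_gene_set_is_the_13_protein_coding_genes():
    assert len(GENES) == 13
    assert {g.label for g in PANGO} == set(GENES)
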