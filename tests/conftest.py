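"""Shared fixtures and independent oracles.

The oracles here are deliberately naive — exhaustive subset enumeration,
literal duplicate-then-delete simulation, brute-force labeling search —
and independent of the package's production code paths, so they can
vouch for the optimized implementations on small inputs.
"""

from __future__ import annotations

import itertools
import random

import pytest

from mitorder.genes import GENES
from mitorder.orders import PANGO, SignedGene, SignedGeneOrder


@pytest.fixture(scope="session")
def pango() -> SignedGeneOrder:
    return PANGO


def random_order(rng: random.Random) -> SignedGeneOrder:
    """A uniformly shuffled, uniformly signed order."""
    labels = list(GENES)
    rng.shuffle(labels)
    return SignedGeneOrder(
        tuple(SignedGene(l, rng.choice((1, -1))) for l in labels)
    )


@pytest.fixture
def order_factory():
    return random_order


# ---------------------------------------------------------------------------
# oracle: common intervals by exhaustive subset enumeration


def oracle_common_intervals(a: SignedGeneOrder, b: SignedGeneOrder) -> set[frozenset[str]]:
    """All non-trivial gene sets contiguous in both linearizations,
    checked subset by subset over the full powerset (2^13)."""
    pos_a = {g.label: k for k, g in enumerate(a)}
    pos_b = {g.label: k for k, g in enumerate(b)}
    out: set[frozenset[str]] = set()
    for r in range(2, 13):  # exclude singletons and the full set
        for subset in itertools.combinations(GENES, r):
            pa = sorted(pos_a[g] for g in subset)
            pb = sorted(pos_b[g] for g in subset)
            if pa[-1] - pa[0] + 1 == r and pb[-1] - pb[0] + 1 == r:
                out.add(frozenset(subset))
    return out


# ---------------------------------------------------------------------------
# oracle: minimum deletion sets by exhaustive subset enumeration


def oracle_min_deletion_sets(
    order: SignedGeneOrder, reference: SignedGeneOrder
) -> tuple[int, list[tuple[str, ...]]]:
    """All minimum-cardinality gene sets whose deletion from both signed
    sequences leaves identical remainders.  Returns (min size, sorted
    flag tuples)."""
    seq_o = [(g.label, g.strand) for g in order]
    seq_r = [(g.label, g.strand) for g in reference]
    for k in range(0, 14):
        hits = []
        for subset in itertools.combinations(GENES, k):
            drop = set(subset)
            ro = [x for x in seq_o if x[0] not in drop]
            rr = [x for x in seq_r if x[0] not in drop]
            if ro == rr:
                hits.append(tuple(sorted(subset)))
        if hits:
            return k, sorted(hits)
    raise AssertionError("unreachable: deleting everything always works")


# ---------------------------------------------------------------------------
# oracle: one-step TDRL by literal duplicate-then-delete simulation


def oracle_tdrl_results(a: SignedGeneOrder) -> set:
    """Canonical forms of every order reachable from ``a`` by one TDRL,
    via literal tandem duplication of each arc and every loss pattern.

    Rotation-invariance of the circle is delegated to the package's
    canonical form (tested separately); the TDRL semantics themselves are
    simulated literally on the doubled sequence.
    """
    from mitorder.orders import _canonical_tuple

    genes = a.genes
    results = set()
    for s in range(13):
        rot = genes[s:] + genes[:s]
        for L in range(2, 14):
            arc, rest = rot[:L], rot[L:]
            for pattern in itertools.product((1, 2), repeat=L):
                if len(set(pattern)) < 2:
                    continue
                doubled = list(zip(arc, itertools.repeat(1))) + list(
                    zip(arc, itertools.repeat(2))
                )
                kept = tuple(
                    g
                    for k, (g, copy) in enumerate(doubled)
                    if pattern[k % L] == copy
                )
                results.add(_canonical_tuple(kept + rest))
    results.discard(a.canonical_form)
    return results


def oracle_tdrl_one_step(a: SignedGeneOrder, b: SignedGeneOrder) -> bool:
    return b.canonical_form in oracle_tdrl_results(a)


# ---------------------------------------------------------------------------
# oracle: Fitch parsimony score by brute-force labeling enumeration


def oracle_parsimony_score(tree, tip_states: dict[str, str]) -> int:
    """Minimum number of state changes over all internal labelings."""
    states = sorted(set(tip_states.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    def node_key(n):
        return n.taxon.label if n.is_leaf() else id(n)

    best = None
    for labeling in itertools.product(states, repeat=len(internals)):
        assigned = {id(n): s for n, s in zip(internals, labeling)}
        changes = 0
        for n in tree.preorder_node_iter():
            if n is tree.seed_node:
                continue
            s_child = (
                tip_states[n.taxon.label] if n.is_leaf() else assigned[id(n)]
            )
            s_parent = assigned[id(n.parent_node)]
            if s_child != s_parent:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


# ---------------------------------------------------------------------------
# helpers: planting event chains


def plant_events(order: SignedGeneOrder, kinds, seed: int):
    """Apply a chain of freshly drawn events; returns (events, result)."""
    import numpy as np

    from mitorder.events import apply_event
    from mitorder.simulate import draw_event

    rng = np.random.default_rng(seed)
    events = []
    cur = order
    for kind in kinds:
        ev = draw_event(cur, kind, rng)
        events.append(ev)
        cur = apply_event(cur, ev)
    return events, cur
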