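"""Minimal rearrangement scenarios, common intervals, TDRL polarity.

The scenario model follows the common-interval rearrangement-explorer
contract: between two orders over the same 13 genes, find event series of
minimal length (bounded, default 3 steps) under the four event classes,
preferring — among equal-length alternatives — scenarios with fewer TDRL,
then fewer iT, then fewer I events, then the lexicographically smallest
encoding.  The bound of three matches the largest distance observed among
amphipod protein-coding gene orders; deeper histories are reported as
"distance exceeds bound" rather than guessed.

Similarity between two orders is summarized by the number of non-trivial
common intervals (NSCI): gene sets contiguous in both cox1-anchored
linearizations, signs ignored, excluding singletons and the full set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine as eng
from .events import (
    RearrangementEvent,
    apply_events,
    event_from_positional,
)
from .orders import SignedGeneOrder, orders_equal

__all__ = [
    "RearrangementScenario",
    "ScenarioInference",
    "CommonIntervalSummary",
    "DirectionReport",
    "infer_scenarios",
    "rearrangement_distance",
    "common_intervals",
    "tdrl_reachable_one_step",
    "ancestral_direction",
]


def _row(order: SignedGeneOrder) -> np.ndarray:
    return eng.row_from_pairs([(g.label, g.strand) for g in order])


def _order(row: np.ndarray) -> SignedGeneOrder:
    return SignedGeneOrder.from_pairs(eng.pairs_from_row(row))


@dataclass(frozen=True)
class RearrangementScenario:
    """An ordered event series transforming source into target."""

    source: SignedGeneOrder
    target: SignedGeneOrder
    events: tuple[RearrangementEvent, ...]

    @property
    def steps(self) -> int:
        return len(self.events)

    def replay(self) -> SignedGeneOrder:
        return apply_events(self.source, self.events)

    def replays_correctly(self) -> bool:
        return orders_equal(self.replay(), self.target)

    def kind_counts(self) -> dict[str, int]:
        counts = {"T": 0, "I": 0, "iT": 0, "TDRL": 0}
        for ev in self.events:
            counts[ev.kind] += 1
        return counts

    def ranking_key(self) -> tuple:
        c = self.kind_counts()
        return (c["TDRL"], c["iT"], c["I"], tuple(str(e) for e in self.events))

    def __str__(self) -> str:
        return ";".join(str(e) for e in self.events) if self.events else "(identity)"


@dataclass
class ScenarioInference:
    """All (or a capped, deterministic subset of) minimal scenarios."""

    source: SignedGeneOrder
    target: SignedGeneOrder
    max_steps: int
    scenarios: list[RearrangementScenario] = field(default_factory=list)
    min_steps: Optional[int] = None
    exceeded_bound: bool = False
    truncated: bool = False

    @property
    def preferred(self) -> Optional[RearrangementScenario]:
        if not self.scenarios:
            return None
        return min(self.scenarios, key=lambda s: s.ranking_key())

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)


def _edge_events(x_row: np.ndarray, z_row: np.ndarray) -> list[RearrangementEvent]:
    """All witness events for an adjacent pair, labelled in x's frame."""
    x_order = _order(x_row)
    return [
        event_from_positional(x_order, pe)
        for pe in eng.events_between(x_row, z_row)
    ]


def infer_scenarios(
    a: SignedGeneOrder,
    b: SignedGeneOrder,
    max_steps: int = 3,
    all_minimal: bool = True,
    max_scenarios: int = 200,
) -> ScenarioInference:
    """Find minimal event scenarios from a to b (bounded search, <= 3).

    The search is complete for the four event classes, so ``min_steps`` is
    the exact bounded distance.  With ``all_minimal=False`` only one
    witness path is reconstructed (faster at depth 3); with
    ``all_minimal=True`` alternative minimal scenarios are enumerated up
    to ``max_scenarios`` (TDRL witnesses reduced to minimal duplicated
    arcs), with ``truncated`` flagging any cap.
    """
    res = ScenarioInference(source=a, target=b, max_steps=max_steps)
    a_row, b_row = _row(a), _row(b)
    found = eng.search(a_row, b_row, max_steps=max_steps, need_all=all_minimal)
    if found.distance is None:
        res.exceeded_bound = True
        return res
    res.min_steps = found.distance

    def add(events: tuple[RearrangementEvent, ...]) -> bool:
        """Append a scenario; False once the cap is hit."""
        if len(res.scenarios) >= max_scenarios:
            res.truncated = True
            return False
        res.scenarios.append(RearrangementScenario(a, b, events))
        return True

    if found.distance == 0:
        add(())
    elif found.distance == 1:
        for ev in _edge_events(a_row, b_row):
            if not add((ev,)):
                break
    elif found.distance == 2:
        for x_row in found.midpoints:
            e1 = _edge_events(a_row, x_row)
            e2 = _edge_events(x_row, b_row)
            stop = False
            for ev1, ev2 in itertools.product(e1, e2):
                if not add((ev1, ev2)):
                    stop = True
                    break
            if stop:
                break
    else:  # distance == 3
        stop = False
        for x_row, z_row in found.pairs:
            e1 = _edge_events(a_row, x_row)
            e2 = _edge_events(x_row, z_row)
            e3 = _edge_events(z_row, b_row)
            for ev1, ev2, ev3 in itertools.product(e1, e2, e3):
                if not add((ev1, ev2, ev3)):
                    stop = True
                    break
            if stop:
                break
        if not all_minimal:
            res.truncated = True

    res.scenarios.sort(key=lambda s: s.ranking_key())
    return res


def rearrangement_distance(
    a: SignedGeneOrder, b: SignedGeneOrder, max_steps: int = 3
) -> Optional[int]:
    """Exact bounded event distance, or None when it exceeds ``max_steps``."""
    found = eng.search(_row(a), _row(b), max_steps=max_steps, need_all=False)
    return found.distance


# ---------------------------------------------------------------------------
# common intervals


@dataclass(frozen=True)
class CommonIntervalSummary:
    intervals: frozenset[frozenset[str]]
    nsci: int


def common_intervals(a: SignedGeneOrder, b: SignedGeneOrder) -> CommonIntervalSummary:
    """Non-trivial gene sets contiguous in both canonical linearizations.

    Signs are ignored (inversions are the event model's business);
    singletons and the full 13-gene set — common to every pair — are
    excluded, so nsci is 0 for totally scrambled pairs and maximal (77)
    iff the unsigned label sequences coincide.
    """
    la = a.labels()
    pos_b = {g.label: k for k, g in enumerate(b)}
    out: set[frozenset[str]] = set()
    for i in range(13):
        lo = hi = pos_b[la[i]]
        for j in range(i + 1, 13):
            p = pos_b[la[j]]
            lo, hi = min(lo, p), max(hi, p)
            size = j - i + 1
            if size == 13:
                continue
            if hi - lo + 1 == size:
                out.add(frozenset(la[i : j + 1]))
    return CommonIntervalSummary(intervals=frozenset(out), nsci=len(out))


# ---------------------------------------------------------------------------
# TDRL reachability and polarity


def tdrl_reachable_one_step(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> tuple[bool, Optional[RearrangementEvent]]:
    """Is b exactly one TDRL away from a?  Returns (flag, witness).

    TDRL never flips strands, so any strand difference is an immediate no.
    The witness (when any) uses the minimal duplicated arc.
    """
    a_row, b_row = _row(a), _row(b)
    if not eng.tdrl_feasible(a_row, b_row):
        return False, None
    witnesses = eng.tdrl_events_between(a_row, eng.code_of(b_row))
    if not witnesses:
        return False, None
    return True, event_from_positional(a, witnesses[0])


@dataclass(frozen=True)
class DirectionReport:
    """TDRL-polarity comparison between two orders.

    ``direction`` is "forward" when the a -> b TDRL-bearing scenario is
    strictly shorter (supporting a as ancestral), "reverse" for the
    opposite, "uninformative" on ties or when neither direction admits a
    TDRL-bearing scenario within the bound.
    """

    direction: str
    steps_forward: Optional[int]
    steps_reverse: Optional[int]
    note: str = ""


def ancestral_direction(
    a: SignedGeneOrder, b: SignedGeneOrder, max_steps: int = 3
) -> DirectionReport:
    """Polarize two orders by TDRL asymmetry.

    TDRL is the one event class that cannot simply be undone by an event
    of the same class, so when the shortest TDRL-bearing scenario is
    cheaper in one direction, the cheaper source is supported as the
    ancestral state.
    """
    if orders_equal(a, b):
        return DirectionReport("uninformative", None, None, "orders identical")
    a_row, b_row = _row(a), _row(b)
    fwd = eng.min_steps_with_tdrl(a_row, b_row, max_steps)
    # the reverse search only matters up to the forward result: anything
    # deeper cannot flip the verdict
    rev = eng.min_steps_with_tdrl(b_row, a_row, min(max_steps, fwd or max_steps))
    if fwd is None and rev is None:
        return DirectionReport(
            "uninformative", None, None, "no TDRL-bearing scenario within bound"
        )
    if rev is None or (fwd is not None and fwd < rev):
        return DirectionReport("forward", fwd, rev)
    if fwd is None or rev < fwd:
        return DirectionReport("reverse", fwd, rev)
    return DirectionReport(
        "uninformative", fwd, rev, "equal TDRL-bearing scenario lengths"
    )
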