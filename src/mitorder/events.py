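"""Rearrangement events and their replay semantics.

Four event classes transform one circular gene order into another:

* ``T`` (transposition) — a contiguous segment moves elsewhere on the same
  coding strand.
* ``I`` (inversion) — a contiguous segment is reversed in place onto the
  other coding strand (every strand in the segment flips).
* ``iT`` (inverse transposition) — the segment moves *and* is reversed
  onto the other strand.
* ``TDRL`` (tandem duplication – random loss) — a contiguous segment is
  duplicated in tandem and one copy of each duplicated gene is lost; genes
  kept from the first copy precede genes kept from the second copy, each
  group in its original relative order, and no strand changes.  TDRL is
  the only class that is not self-inverse, which is what lets it polarize
  ancestry between two orders.

Events are described by gene labels (not positions), so a stored event can
be replayed on any order in which its segment is contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from . import _engine as eng
from ._engine import PositionalEvent
from .orders import SignedGene, SignedGeneOrder

__all__ = [
    "RearrangementEvent",
    "InvalidEventError",
    "apply_event",
    "apply_events",
    "enumerate_single_events",
]

EVENT_KINDS = ("T", "I", "iT", "TDRL")


class InvalidEventError(ValueError):
    """The event cannot be applied to the given order."""


@dataclass(frozen=True)
class RearrangementEvent:
    """One typed rearrangement event.

    ``segment`` lists the affected genes in their source order.  For T and
    iT, ``destination`` names the gene after which the (possibly inverted)
    segment is reinserted, reading the circle in canonical direction.  For
    TDRL, ``loss_pattern`` records per segment gene whether the first (1)
    or second (2) tandem copy survived.
    """

    kind: str
    segment: tuple[str, ...]
    destination: Optional[str] = None
    loss_pattern: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidEventError(f"unknown event kind {self.kind!r}")
        if not self.segment:
            raise InvalidEventError("segment must be non-empty")
        if self.kind in ("T", "iT"):
            if self.destination is None:
                raise InvalidEventError(f"{self.kind} requires a destination")
            if self.destination in self.segment:
                raise InvalidEventError("destination lies inside the moved segment")
        if self.kind == "TDRL":
            lp = self.loss_pattern
            if lp is None or len(lp) != len(self.segment):
                raise InvalidEventError("TDRL needs one loss choice per segment gene")
            if set(lp) - {1, 2}:
                raise InvalidEventError("loss pattern entries must be 1 or 2")
            if len(set(lp)) < 2:
                raise InvalidEventError(
                    "degenerate loss pattern: all genes kept from the same copy"
                )

    # -- encoding -------------------------------------------------------
    def __str__(self) -> str:
        seg = (
            self.segment[0]
            if len(self.segment) == 1
            else f"{self.segment[0]}..{self.segment[-1]}"
        )
        if self.kind == "I":
            return f"I[{seg}]"
        if self.kind in ("T", "iT"):
            return f"{self.kind}[{seg}->after {self.destination}]"
        second = ",".join(
            g for g, c in zip(self.segment, self.loss_pattern) if c == 2
        )
        return f"TDRL[{seg};second:{second}]"

    def sort_key(self) -> tuple:
        return (self.kind, self.segment, self.destination or "", self.loss_pattern or ())


def _locate_segment(genes: tuple[SignedGene, ...], segment: tuple[str, ...]) -> int:
    labels = [g.label for g in genes]
    L = len(segment)
    for s in range(13):
        if all(labels[(s + k) % 13] == segment[k] for k in range(L)):
            return s
    raise InvalidEventError(
        f"segment {'..'.join(segment)} is not contiguous in {','.join(labels)}"
    )


def apply_event(order: SignedGeneOrder, event: RearrangementEvent) -> SignedGeneOrder:
    """Replay one event on an order; the result is again a valid order."""
    genes = order.genes
    s = _locate_segment(genes, event.segment)
    L = len(event.segment)
    rot = genes[s:] + genes[:s]  # segment now occupies rot[:L]
    seg, rest = list(rot[:L]), list(rot[L:])

    if event.kind == "I":
        new = [g.flipped() for g in reversed(seg)] + rest
    elif event.kind in ("T", "iT"):
        if event.kind == "iT":
            seg = [g.flipped() for g in reversed(seg)]
        d = next(
            (k for k, g in enumerate(rest) if g.label == event.destination), None
        )
        if d is None:
            raise InvalidEventError(
                f"destination {event.destination!r} not found outside the segment"
            )
        new = rest[: d + 1] + seg + rest[d + 1 :]
    else:  # TDRL
        first = [g for g, c in zip(seg, event.loss_pattern) if c == 1]
        second = [g for g, c in zip(seg, event.loss_pattern) if c == 2]
        new = first + second + rest
    return SignedGeneOrder(tuple(new))


def apply_events(order: SignedGeneOrder, events) -> SignedGeneOrder:
    for ev in events:
        order = apply_event(order, ev)
    return order


# ---------------------------------------------------------------------------
# positional <-> labelled conversion (engine frame is the source
# canonical linearization)


def event_from_positional(source: SignedGeneOrder, pe: PositionalEvent) -> RearrangementEvent:
    g = source.genes
    if pe.kind in ("T", "I"):
        segment = tuple(x.label for x in g[pe.i : pe.j + 1])
        if pe.kind == "I":
            return RearrangementEvent("I", segment)
        rem = [x.label for k, x in enumerate(g) if not (pe.i <= k <= pe.j)]
        dest = rem[pe.g - 1] if pe.g > 0 else rem[-1]
        return RearrangementEvent("T", segment, destination=dest)
    if pe.kind == "iT":
        # circular arc: i = start, j = length; insert after the g-th
        # remaining gene counted from the arc end
        segment = tuple(g[(pe.i + k) % 13].label for k in range(pe.j))
        dest = g[(pe.i + pe.j + pe.g) % 13].label
        return RearrangementEvent("iT", segment, destination=dest)
    # TDRL: i = arc start (rotation), j = arc length, g = loss mask
    segment = tuple(g[(pe.i + k) % 13].label for k in range(pe.j))
    pattern = tuple(2 if (pe.g >> k) & 1 else 1 for k in range(pe.j))
    return RearrangementEvent("TDRL", segment, loss_pattern=pattern)


def enumerate_single_events(
    order: SignedGeneOrder, kinds: tuple[str, ...] = EVENT_KINDS
) -> Iterator[tuple[RearrangementEvent, SignedGeneOrder]]:
    """Yield every distinct order reachable by one event, with a witness.

    Results are deduplicated by canonical form (one witness event each,
    the first in table order) and never include the input itself.  TDRL
    witnesses are reduced to their minimal duplicated arc.
    """
    t = eng.tables()
    row = eng.row_from_pairs([(x.label, x.strand) for x in order])
    self_code = eng.code_of(row)
    seen = {self_code}

    if any(k in kinds for k in ("T", "I", "iT")):
        rows = eng.succ_tiit_rows(row)
        codes = eng.codes_of(rows)
        for k, desc in enumerate(t.TIIT_DESC):
            if desc.kind not in kinds:
                continue
            c = int(codes[k])
            if c in seen:
                continue
            seen.add(c)
            yield (
                event_from_positional(order, desc),
                SignedGeneOrder.from_pairs(eng.pairs_from_row(rows[k])),
            )

    if "TDRL" in kinds:
        rows = eng.succ_tdrl_rows(row)
        codes = eng.codes_of(rows)
        uniq, first = np.unique(codes, return_index=True)
        for c, k in sorted(zip(uniq.tolist(), first.tolist()), key=lambda p: p[1]):
            if c in seen:
                continue
            seen.add(c)
            pe = eng.reduce_tdrl_witness(k)
            if pe is None:
                continue
            yield (
                event_from_positional(order, pe),
                SignedGeneOrder.from_pairs(eng.pairs_from_row(rows[k])),
            )
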