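"""Repositioned-gene scoring against a reference order and
simple/complex classification of transitions.

The scoring formalizes the manual 0/1 annotation used in comparative
mitogenomics: lay the cox1-anchored linearizations of an order and the
reference (by default the Pancrustacean pattern) side by side, find the
conserved blocks, and mark with 1 every gene whose position — or coding
strand — changed relative to those blocks.  Formally the flagged genes
are a minimum-cardinality set whose deletion from both sequences leaves
identical signed sequences; the surviving genes, in maximal runs
contiguous in both orders, are the conserved blocks.  A gene on the
opposite strand can never survive, so strand changes always score 1.

A transition between two orders is *complex* when its preferred minimal
scenario needs two or more steps, mixes event types, or contains a TDRL;
otherwise it is *simple*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genes import GENES
from .orders import PANGO, GeneOrderClass, SignedGeneOrder
from .scenarios import ScenarioInference

__all__ = [
    "RepositionScore",
    "ComplexityVerdict",
    "reposition_score",
    "aggregate_reposition_counts",
    "classify_transition",
]


@dataclass(frozen=True)
class RepositionScore:
    """Per-gene 0/1 reposition flags of one order against a reference."""

    flags: Mapping[str, int]
    blocks: tuple[tuple[str, ...], ...]

    @property
    def count(self) -> int:
        return sum(self.flags.values())

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, f in self.flags.items() if f))

    @property
    def kept(self) -> tuple[str, ...]:
        return tuple(g for block in self.blocks for g in block)


def _all_max_increasing_chains(values: Sequence[int]) -> list[tuple[int, ...]]:
    """All maximum-length strictly increasing subsequences (as index tuples)."""
    n = len(values)
    if n == 0:
        return [()]
    f = [1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i]:
                f[i] = max(f[i], f[j] + 1)
    best = max(f)
    out: list[tuple[int, ...]] = []

    def back(i: int, chain: list[int]) -> None:
        chain.append(i)
        if f[i] == 1:
            out.append(tuple(reversed(chain)))
        else:
            for j in range(i):
                if f[j] == f[i] - 1 and values[j] < values[i]:
                    back(j, chain)
        chain.pop()

    for i in range(n):
        if f[i] == best:
            back(i, [])
    return out


def reposition_score(
    order: SignedGeneOrder, reference: SignedGeneOrder = PANGO
) -> RepositionScore:
    """Flag the minimum set of genes whose removal reconciles the orders.

    Among equal-size minimal flag sets the lexicographically smallest
    (by sorted gene names) is chosen; genes on the opposite strand are
    always flagged because they can never be part of a shared signed
    block.
    """
    pos_ref = {g.label: k for k, g in enumerate(reference)}
    strand_ref = {g.label: g.strand for g in reference}

    keepable = [g.label for g in order if g.strand == strand_ref[g.label]]
    ref_positions = [pos_ref[l] for l in keepable]
    chains = _all_max_increasing_chains(ref_positions)

    best_kept: Optional[tuple[str, ...]] = None
    best_flagged: Optional[tuple[str, ...]] = None
    for chain in chains:
        kept = tuple(keepable[i] for i in chain)
        flagged = tuple(sorted(set(GENES) - set(kept)))
        if best_flagged is None or flagged < best_flagged:
            best_flagged, best_kept = flagged, kept

    flags = {g: (1 if g in best_flagged else 0) for g in GENES}

    # conserved blocks: maximal kept runs adjacent in both linearizations
    pos_ord = {g.label: k for k, g in enumerate(order)}
    blocks: list[tuple[str, ...]] = []
    current: list[str] = []
    for label in best_kept:
        if current and (
            pos_ord[label] == pos_ord[current[-1]] + 1
            and pos_ref[label] == pos_ref[current[-1]] + 1
        ):
            current.append(label)
        else:
            if current:
                blocks.append(tuple(current))
            current = [label]
    if current:
        blocks.append(tuple(current))
    return RepositionScore(flags=flags, blocks=tuple(blocks))


def aggregate_reposition_counts(
    scored: Sequence[tuple[GeneOrderClass, RepositionScore]],
    grouping: Optional[Mapping[str, str]] = None,
    unit: str = "per_GO",
) -> pd.DataFrame:
    """Per-gene reposition counts, optionally split by species group.

    ``unit="per_GO"`` counts each unique order class once per group it has
    members in (so a class spanning groups contributes to each);
    ``unit="per_species"`` counts member species.  Returns a tidy frame
    with columns gene, group, count covering all 13 genes.
    """
    if unit not in ("per_GO", "per_species"):
        raise ValueError(f"unknown unit {unit!r}")
    if grouping is not None:
        missing = sorted(
            {sp for cls, _ in scored for sp in cls.members if sp not in grouping}
        )
        if missing:
            raise KeyError(f"species missing from grouping: {', '.join(missing)}")

    counts: dict[tuple[str, str], int] = {}
    groups: set[str] = set()
    for cls, score in scored:
        member_groups: dict[str, int] = {}
        for sp in cls.members:
            grp = grouping[sp] if grouping is not None else "all"
            member_groups[grp] = member_groups.get(grp, 0) + 1
        groups.update(member_groups)
        for gene, flag in score.flags.items():
            if not flag:
                continue
            for grp, n_members in member_groups.items():
                inc = 1 if unit == "per_GO" else n_members
                counts[(gene, grp)] = counts.get((gene, grp), 0) + inc

    rows = [
        {"gene": gene, "group": grp, "count": counts.get((gene, grp), 0)}
        for gene in GENES
        for grp in sorted(groups) or ["all"]
    ]
    df = pd.DataFrame(rows, columns=["gene", "group", "count"])
    df.attrs["unit"] = unit
    return df


@dataclass(frozen=True)
class ComplexityVerdict:
    """Simple/complex call for one gene-order transition."""

    verdict: str                      # "simple" | "complex"
    triggered: frozenset[str] = field(default_factory=frozenset)
    stable: bool = True               # do all minimal scenarios agree?
    note: str = ""

    def __post_init__(self) -> None:
        expected = "complex" if self.triggered else "simple"
        if self.verdict != expected:
            raise ValueError("verdict must follow the triggered criteria")


_CRITERIA = ("multi_step", "mixed_types", "has_tdrl")


def _criteria_for(steps: int, kinds: Sequence[str]) -> frozenset[str]:
    crit = set()
    if steps >= 2:
        crit.add("multi_step")
    if len(set(kinds)) > 1:
        crit.add("mixed_types")
    if "TDRL" in kinds:
        crit.add("has_tdrl")
    return frozenset(crit)


def classify_transition(inference: ScenarioInference) -> ComplexityVerdict:
    """Classify a transition from its minimal scenarios.

    The verdict reads the preferred scenario; ``stable`` is False when
    some other minimal scenario would flip it.  A transition whose
    distance exceeds the search bound is complex via multi_step.
    """
    if inference.exceeded_bound or not inference.scenarios:
        return ComplexityVerdict(
            "complex",
            frozenset({"multi_step"}),
            note=f"distance exceeds max_steps={inference.max_steps}",
        )
    pref = inference.preferred
    crit = _criteria_for(pref.steps, [e.kind for e in pref.events])
    verdict = "complex" if crit else "simple"
    stable = all(
        (
            "complex"
            if _criteria_for(s.steps, [e.kind for e in s.events])
            else "simple"
        )
        == verdict
        for s in inference.scenarios
    )
    return ComplexityVerdict(verdict, crit, stable=stable)
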