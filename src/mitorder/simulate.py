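"""Seeded synthetic datasets with planted rearrangement histories.

The generator emulates the structure of a comparative amphipod-like
dataset: a rooted species tree whose root carries the Pancrustacean
pattern, one *conserved* clade evolving without any rearrangement (the
analogue of a lineage whose gene order never moved), one *labile* clade
whose stem carries a TDRL and whose tips accumulate further events (the
analogue of a rearrangement hotspot), an optional pair of distant tips
forced to share one identical derived order (homoplasy), and background
branches drawing an independent Poisson number of events each.  Every
random choice is driven by a per-branch generator seeded from the global
seed and the branch id, so local edits never reshuffle the rest of a
simulation and equal seeds give byte-identical output.

Event parameters (segments, destinations, loss patterns) are drawn
uniformly over valid choices — no biological weighting is claimed, and
uniformity exercises edge segments well.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .events import InvalidEventError, RearrangementEvent, apply_event, apply_events
from .genes import GENES
from .orders import PANGO, SignedGeneOrder, orders_equal
from .phylo import scan_hotspot_clades

__all__ = [
    "SimulationSpec",
    "PlantedHistory",
    "simulate_history",
    "write_fixture_genbank",
]

EVENT_KINDS = ("T", "I", "iT", "TDRL")

#: Approximate coding lengths (bp) used for fixture records.
_GENE_LENGTHS = {
    "atp6": 675, "atp8": 159, "cox1": 1536, "cox2": 684, "cox3": 786,
    "cytb": 1137, "nad1": 939, "nad2": 1020, "nad3": 351, "nad4": 1338,
    "nad4l": 297, "nad5": 1719, "nad6": 510,
}

_PRODUCTS = {
    "atp6": "ATP synthase F0 subunit 6",
    "atp8": "ATP synthase F0 subunit 8",
    "cox1": "cytochrome c oxidase subunit I",
    "cox2": "cytochrome c oxidase subunit II",
    "cox3": "cytochrome c oxidase subunit III",
    "cytb": "cytochrome b",
    "nad1": "NADH dehydrogenase subunit 1",
    "nad2": "NADH dehydrogenase subunit 2",
    "nad3": "NADH dehydrogenase subunit 3",
    "nad4": "NADH dehydrogenase subunit 4",
    "nad4l": "NADH dehydrogenase subunit 4L",
    "nad5": "NADH dehydrogenase subunit 5",
    "nad6": "NADH dehydrogenase subunit 6",
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_taxa: int = 20
    tree_shape: str = "random-birth"          # or "balanced"
    event_rate: float = 0.3                   # expected events per branch
    type_mix: tuple[float, float, float, float] = (0.5, 0.2, 0.15, 0.15)
    conserved_clade_fraction: float = 0.4
    homoplasy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.tree_shape not in ("balanced", "random-birth"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if len(self.type_mix) != 4 or any(w < 0 for w in self.type_mix):
            raise ValueError("type_mix needs 4 non-negative weights")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        if not (0 <= self.conserved_clade_fraction < 1):
            raise ValueError("conserved_clade_fraction must be in [0, 1)")
        if self.homoplasy and self.n_taxa < 8:
            raise ValueError("homoplasy planting needs n_taxa >= 8")


@dataclass
class PlantedHistory:
    """Ground truth of one simulation."""

    spec: SimulationSpec
    tree: dendropy.Tree
    root_order: SignedGeneOrder
    branch_events: dict[str, list[RearrangementEvent]]
    tip_orders: dict[str, SignedGeneOrder]
    node_orders: dict[str, SignedGeneOrder]
    groups: dict[str, str]                       # species -> group label
    conserved_tips: tuple[str, ...]
    labile_tips: tuple[str, ...]
    labile_stem: str = ""
    homoplasy_pair: Optional[tuple[str, str]] = None
    accessions: dict[str, str] = field(default_factory=dict)

    # -- ground-truth views --------------------------------------------
    def n_planted_classes(self) -> int:
        return len({o.canonical_form for o in self.tip_orders.values()})

    def replay_tips(self) -> dict[str, SignedGeneOrder]:
        """Re-derive every tip order from root + branch events."""
        out: dict[str, SignedGeneOrder] = {}
        node_order = {self._node_id(self.tree.seed_node): self.root_order}
        for node in self.tree.preorder_node_iter():
            nid = self._node_id(node)
            if node is not self.tree.seed_node:
                parent = node_order[self._node_id(node.parent_node)]
                node_order[nid] = apply_events(
                    parent, self.branch_events.get(nid, [])
                )
            if node.is_leaf():
                out[nid] = node_order[nid]
        return out

    def _node_id(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def expected_hotspots(self, min_derived_fraction: float = 0.5):
        """Hotspot clades implied by the *planted* (true) states.

        Uses the same clade-scan definition as the inference path but
        feeds it the planted node orders, so recovery tests compare
        reconstructed states against truth.
        """
        forms: dict = {}
        ids: dict[str, str] = {}
        for nid, order in self.node_orders.items():
            key = order.canonical_form
            if key not in forms:
                forms[key] = f"S{len(forms)}"
            ids[nid] = forms[key]
        return scan_hotspot_clades(
            self.tree, self._node_id, lambda nid: ids.get(nid), min_derived_fraction
        )

    def newick(self) -> str:
        return self.tree.as_string(schema="newick")

    def to_json(self) -> str:
        payload = {
            "spec": {
                "n_taxa": self.spec.n_taxa,
                "tree_shape": self.spec.tree_shape,
                "event_rate": self.spec.event_rate,
                "type_mix": list(self.spec.type_mix),
                "conserved_clade_fraction": self.spec.conserved_clade_fraction,
                "homoplasy": self.spec.homoplasy,
                "seed": self.spec.seed,
            },
            "root_order": str(self.root_order),
            "branch_events": {
                nid: [str(e) for e in evs]
                for nid, evs in sorted(self.branch_events.items())
                if evs
            },
            "tip_orders": {sp: str(o) for sp, o in sorted(self.tip_orders.items())},
            "groups": dict(sorted(self.groups.items())),
            "homoplasy_pair": list(self.homoplasy_pair) if self.homoplasy_pair else None,
            "n_planted_classes": self.n_planted_classes(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# random primitives


def _branch_rng(seed: int, branch_id: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}/{branch_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def draw_event(
    order: SignedGeneOrder, kind: str, rng: np.random.Generator
) -> RearrangementEvent:
    """One random valid, non-identity event of the given kind."""
    labels = [g.label for g in order]
    for _ in range(64):
        if kind in ("T", "I", "iT"):
            L = int(rng.integers(1, 12 if kind == "I" else 11, endpoint=True))
            s = int(rng.integers(0, 12, endpoint=True))
            segment = tuple(labels[(s + k) % 13] for k in range(L))
            if kind == "I":
                ev = RearrangementEvent("I", segment)
            else:
                rest = [l for l in labels if l not in segment]
                dest = rest[int(rng.integers(0, len(rest)))]
                ev = RearrangementEvent(kind, segment, destination=dest)
        else:
            L = int(rng.integers(2, 13, endpoint=True))
            s = int(rng.integers(0, 12, endpoint=True))
            segment = tuple(labels[(s + k) % 13] for k in range(L))
            pattern = tuple(int(c) for c in rng.integers(1, 2, size=L, endpoint=True))
            if len(set(pattern)) < 2:
                continue
            ev = RearrangementEvent("TDRL", segment, loss_pattern=pattern)
        try:
            result = apply_event(order, ev)
        except InvalidEventError:
            continue
        if orders_equal(result, order):
            continue
        if kind == "iT":
            # an iT that lands back in place is indistinguishable from I
            in_place = apply_event(order, RearrangementEvent("I", ev.segment))
            if orders_equal(result, in_place):
                continue
        return ev
    raise RuntimeError(f"could not draw a non-identity {kind} event")


def _draw_kind(rng: np.random.Generator, mix) -> str:
    return EVENT_KINDS[int(rng.choice(4, p=list(mix)))]


# ---------------------------------------------------------------------------
# tree construction


def _random_topology(tips: list[str], rng: np.random.Generator, balanced: bool) -> str:
    if len(tips) == 1:
        return tips[0]
    k = len(tips) // 2 if balanced else int(rng.integers(1, len(tips) - 1, endpoint=True))
    left = _random_topology(tips[:k], rng, balanced)
    right = _random_topology(tips[k:], rng, balanced)
    return f"({left},{right})"


def _build_tree(spec: SimulationSpec, n_cons: int, n_lab: int) -> tuple[dendropy.Tree, list[str]]:
    species = [f"sp{k:02d}" for k in range(1, spec.n_taxa + 1)]
    cons = species[:n_cons]
    lab = species[n_cons : n_cons + n_lab]
    back = species[n_cons + n_lab :]
    rng = _branch_rng(spec.seed, "topology")
    balanced = spec.tree_shape == "balanced"
    half = max(1, len(back) // 2)
    b1 = _random_topology(back[:half], rng, balanced)
    b2 = _random_topology(back[half:], rng, balanced) if back[half:] else None
    lab_nwk = _random_topology(lab, rng, balanced)
    parts = f"({lab_nwk},{b1})" if b2 is None else f"(({lab_nwk},{b1}),{b2})"
    if cons:
        cons_nwk = _random_topology(cons, rng, balanced)
        newick = f"({cons_nwk},{parts});"
    else:
        newick = f"{parts};"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = f"N{k}"
            k += 1
    return tree, species


def simulate_history(spec: SimulationSpec) -> PlantedHistory:
    """Plant a rearrangement history on a synthetic species tree.

    The conserved clade (first ``conserved_clade_fraction`` of taxa,
    including its stem) carries zero events; the labile clade gets a stem
    TDRL plus one extra event on most of its pendant branches; the
    homoplasy pair (one tip in each background subtree, with their root
    paths kept event-free) shares one identical transposition-like event;
    every other branch draws Poisson(``event_rate``) events with kinds
    from ``type_mix`` and uniform valid parameters.
    """
    n_cons = round(spec.n_taxa * spec.conserved_clade_fraction)
    if n_cons == 1:
        n_cons = 2  # a one-tip "clade" is not a clade
    n_lab = min(max(3, spec.n_taxa // 5), spec.n_taxa - n_cons - (4 if spec.homoplasy else 1))
    if n_lab < 3:
        raise ValueError("too few taxa left for a labile clade; lower the conserved fraction")
    tree, species = _build_tree(spec, n_cons, n_lab)
    cons = set(species[:n_cons])
    lab = species[n_cons : n_cons + n_lab]
    back = species[n_cons + n_lab :]

    def node_id(node):
        return node.taxon.label if node.is_leaf() else node.label

    # classify branches
    cons_nodes: set[str] = set()
    if cons:
        mrca = tree.mrca(taxon_labels=sorted(cons))
        cons_nodes = {node_id(n) for n in mrca.preorder_iter()} | {node_id(mrca)}

    frozen: set[str] = set(cons_nodes)
    homoplasy_pair = None
    if spec.homoplasy:
        half = max(1, len(back) // 2)
        h1, h2 = back[0], back[half] if back[half:] else back[-1]
        homoplasy_pair = (h1, h2)
        for h in homoplasy_pair:
            leaf = next(
                l for l in tree.leaf_node_iter() if l.taxon.label == h
            )
            node = leaf
            while node is not None:
                frozen.add(node_id(node))
                node = node.parent_node

    lab_mrca = tree.mrca(taxon_labels=sorted(lab))
    lab_stem = node_id(lab_mrca)
    lab_pendants = [node_id(l) for l in lab_mrca.leaf_iter()]

    branch_events: dict[str, list[RearrangementEvent]] = {}
    node_orders: dict[str, SignedGeneOrder] = {}
    tip_orders: dict[str, SignedGeneOrder] = {}

    hom_event: Optional[RearrangementEvent] = None
    if homoplasy_pair:
        hom_event = draw_event(PANGO, "T", _branch_rng(spec.seed, "homoplasy"))

    for node in tree.preorder_node_iter():
        nid = node_id(node)
        if node is tree.seed_node:
            node_orders[nid] = PANGO
            continue
        parent_order = node_orders[node_id(node.parent_node)]
        rng = _branch_rng(spec.seed, nid)
        events: list[RearrangementEvent] = []
        if homoplasy_pair and nid in homoplasy_pair:
            events = [hom_event]
        elif nid in frozen:
            events = []
        elif nid == lab_stem:
            events = [draw_event(parent_order, "TDRL", rng)]
        elif nid in lab_pendants:
            # extra event on most labile tips => several distinct derived GOs
            if rng.random() < 0.8:
                kind = _draw_kind(rng, spec.type_mix)
                events = [draw_event(parent_order, kind, rng)]
        else:
            n_events = int(rng.poisson(spec.event_rate))
            cur = parent_order
            for _ in range(n_events):
                ev = draw_event(cur, _draw_kind(rng, spec.type_mix), rng)
                events.append(ev)
                cur = apply_event(cur, ev)
        order = apply_events(parent_order, events)
        branch_events[nid] = events
        node_orders[nid] = order
        if node.is_leaf():
            tip_orders[nid] = order

    groups = {
        sp: ("conserved" if sp in cons else "labile" if sp in lab else "background")
        for sp in species
    }
    accessions = {sp: f"SYN{k:04d}" for k, sp in enumerate(species, start=1)}
    return PlantedHistory(
        spec=spec,
        tree=tree,
        root_order=PANGO,
        branch_events=branch_events,
        tip_orders=tip_orders,
        node_orders=node_orders,
        groups=groups,
        conserved_tips=tuple(sorted(cons)),
        labile_tips=tuple(lab),
        labile_stem=lab_stem,
        homoplasy_pair=homoplasy_pair,
        accessions=accessions,
    )


# ---------------------------------------------------------------------------
# GenBank fixtures


def write_fixture_genbank(history: PlantedHistory, path) -> int:
    """Write one synthetic GenBank record per tip; returns the count.

    Each record lays out 13 CDS features according to the tip's planted
    order (synthetic coordinates, random spacers, correct strands) and
    round-trips through the GenBank parser.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for sp in sorted(history.tip_orders):
        order = history.tip_orders[sp]
        rng = _branch_rng(history.spec.seed, f"genbank/{sp}")
        features = []
        pos = int(rng.integers(30, 200))
        for gene in order:
            length = _GENE_LENGTHS[gene.label]
            loc = SimpleLocation(pos, pos + length, strand=gene.strand)
            features.append(
                SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={
                        "gene": [gene.label],
                        "product": [_PRODUCTS[gene.label]],
                        "transl_table": ["5"],
                    },
                )
            )
            pos += length + int(rng.integers(5, 60))
        total = pos + int(rng.integers(30, 200))
        seq = Seq("".join(rng.choice(list("ACGT"), size=total)))
        rec = SeqRecord(
            seq,
            id=history.accessions[sp],
            name=history.accessions[sp],
            description=f"{sp} mitochondrion, complete genome (synthetic)",
        )
        rec.annotations.update(
            molecule_type="DNA", topology="circular", organism=sp,
            data_file_division="INV",
        )
        src = SeqFeature(
            SimpleLocation(0, total, strand=1),
            type="source",
            qualifiers={"organism": [sp], "organelle": ["mitochondrion"]},
        )
        rec.features = [src] + features
        records.append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "genbank")
    return len(records)


def write_metadata_tsv(history: PlantedHistory, path) -> None:
    """Species metadata table: species, accession, group."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mitorder species metadata, schema v1\n")
        fh.write("species\taccession\tgroup\n")
        for sp in sorted(history.groups):
            fh.write(f"{sp}\t{history.accessions[sp]}\t{history.groups[sp]}\n")
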