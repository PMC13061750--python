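"""Gene-order characters on a rooted phylogeny.

Gene-order classes are treated as an unordered multistate character: tips
carry the class of their genome, ancestral states are reconstructed by
Fitch parsimony (every transition costs 1, rearrangement step counts are
reported alongside but do not weight the reconstruction), ambiguous nodes
are resolved conservatively toward the parental state so changes attach
to recent branches, and branches whose parent and child states differ are
annotated with the transition, its minimal scenario and the repositioned
genes.  Clades where several distinct derived orders accumulate are
flagged as rearrangement hotspots.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import dendropy

from .orders import PANGO, GeneOrderClass, SignedGeneOrder
from .scenarios import ScenarioInference, ancestral_direction, infer_scenarios
from .scoring import reposition_score

__all__ = [
    "AnnotatedTree",
    "BranchChange",
    "HotspotClade",
    "EXCLUDED",
    "attach_states",
    "ancestral_states",
    "annotate_branch_changes",
    "find_hotspots",
]

#: Sentinel state for tips present on the tree but excluded from the
#: gene-order analysis (e.g. incomplete genomes kept for the phylogeny).
EXCLUDED = "excluded"


def normalize_label(label: str) -> str:
    """Whitespace/underscore-insensitive tip label, accession suffix
    (anything after ``|``) stripped."""
    label = label.split("|", 1)[0]
    return re.sub(r"[\s_]+", "_", label.strip())


@dataclass
class BranchChange:
    parent: str
    child: str
    source_class: str
    target_class: str
    steps: Optional[int]              # None when distance exceeds the bound
    preferred_scenario: str
    genes_moved: tuple[str, ...]      # reposition flags gained on this branch
    exceeded_bound: bool = False


@dataclass
class HotspotClade:
    root_node: str
    tips: tuple[str, ...]
    unique_GOs: frozenset[str]        # derived classes within the clade
    ancestral_GO: str


@dataclass
class AnnotatedTree:
    """A rooted tree plus everything the gene-order analysis hangs on it."""

    tree: dendropy.Tree
    tip_states: dict[str, str]
    classes: dict[str, GeneOrderClass]
    node_states: dict[str, frozenset[str]] = field(default_factory=dict)
    resolved: dict[str, str] = field(default_factory=dict)
    branch_changes: dict[str, BranchChange] = field(default_factory=dict)
    hotspots: list[HotspotClade] = field(default_factory=list)
    parsimony_score: Optional[int] = None
    notes: list[str] = field(default_factory=list)

    # -- helpers --------------------------------------------------------
    def node_id(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return normalize_label(node.taxon.label)
        return node.label

    def informative_tips(self, node: dendropy.Node) -> list[str]:
        return [
            self.node_id(t)
            for t in node.leaf_iter()
            if self.tip_states.get(self.node_id(t), EXCLUDED) != EXCLUDED
        ]

    def excluded_tips(self) -> list[str]:
        return sorted(k for k, v in self.tip_states.items() if v == EXCLUDED)

    def representative(self, class_id: str) -> SignedGeneOrder:
        return self.classes[class_id].representative

    def to_annotated_newick(self) -> str:
        """Newick with node comments carrying state and hotspot flags."""
        hot_roots = {h.root_node for h in self.hotspots}
        for node in self.tree.preorder_node_iter():
            nid = self.node_id(node)
            parts = []
            state = self.resolved.get(nid) or self.tip_states.get(nid)
            if state:
                parts.append(f"state={state.replace(' ', '')}")
            if nid in hot_roots:
                parts.append("hotspot=yes")
            node.annotations.drop()
            for p in parts:
                k, v = p.split("=")
                node.annotations.add_new(k, v)
        return self.tree.as_string(schema="newick", suppress_annotations=False)


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        try:
            if "(" in text:
                t = dendropy.Tree.get(data=text, schema="newick")
            else:
                t = dendropy.Tree.get(path=text, schema="newick")
        except Exception as exc:
            raise ValueError(f"invalid newick tree: {exc}") from exc
    t.is_rooted = True
    return t


def attach_states(
    tree,
    assignment: Mapping[str, str],
    classes: Mapping[str, GeneOrderClass],
) -> AnnotatedTree:
    """Bind species -> gene-order-class assignments to the tree's tips.

    ``tree`` may be a dendropy Tree, a newick string, or a path to one.
    Matching is exact after whitespace/underscore normalization and
    accession-suffix stripping; species in the assignment but absent from
    the tree are an error; tips without an assignment are kept with an
    explicit "excluded" state (mirroring genomes retained for the
    phylogeny but excluded from the gene-order analysis).
    """
    t = _load_tree(tree)
    tip_labels = [normalize_label(l.taxon.label) for l in t.leaf_node_iter()]
    dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {', '.join(dupes)}")

    norm_assignment = {normalize_label(k): v for k, v in assignment.items()}
    orphans = sorted(set(norm_assignment) - set(tip_labels))
    if orphans:
        raise ValueError(
            f"assignment names species absent from the tree: {', '.join(orphans)}"
        )

    k = 0
    for node in t.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"N{k}"
        k += 1

    tip_states = {
        l: norm_assignment.get(l, EXCLUDED) for l in tip_labels
    }
    return AnnotatedTree(tree=t, tip_states=tip_states, classes=dict(classes))


def ancestral_states(
    atree: AnnotatedTree,
    resolve: str = "parent",
    tdrl_tiebreak: bool = False,
) -> AnnotatedTree:
    """Fitch parsimony on gene-order identity, with conservative resolution.

    Downpass: a leaf contributes its class; an internal node takes the
    intersection of its informative children's sets when non-empty, else
    the union (counting one change).  Excluded tips are ignored.

    Resolution (preorder): a node whose set contains its parent's resolved
    state keeps that state (changes are pushed toward the tips); otherwise
    the candidate carried by most informative tips in the subtree wins,
    ties broken by class id.  With ``tdrl_tiebreak``, a two-way tie at the
    root is additionally polarized by TDRL asymmetry between the two
    candidate orders, recorded as a secondary-evidence note.
    """
    if resolve not in ("parent",):
        raise ValueError(f"unknown resolution mode {resolve!r}")
    informative = {
        tip: s for tip, s in atree.tip_states.items() if s != EXCLUDED
    }
    if not informative:
        raise ValueError("no assigned tips: cannot reconstruct ancestral states")

    node_sets: dict[str, frozenset[str]] = {}
    support: dict[str, dict[str, int]] = {}
    score = 0
    for node in atree.tree.postorder_node_iter():
        nid = atree.node_id(node)
        if node.is_leaf():
            s = atree.tip_states.get(nid, EXCLUDED)
            if s == EXCLUDED:
                node_sets[nid] = frozenset()
                support[nid] = {}
            else:
                node_sets[nid] = frozenset({s})
                support[nid] = {s: 1}
            continue
        child_sets = [
            node_sets[atree.node_id(c)]
            for c in node.child_nodes()
            if node_sets[atree.node_id(c)]
        ]
        sup: dict[str, int] = {}
        for c in node.child_nodes():
            for st, n in support[atree.node_id(c)].items():
                sup[st] = sup.get(st, 0) + n
        support[nid] = sup
        if not child_sets:
            node_sets[nid] = frozenset()
            continue
        inter = frozenset.intersection(*child_sets)
        if inter:
            node_sets[nid] = inter
        else:
            node_sets[nid] = frozenset.union(*child_sets)
            score += 1

    resolved: dict[str, str] = {}
    root = atree.tree.seed_node

    def pick(nid: str, candidates: frozenset[str]) -> str:
        return min(candidates, key=lambda s: (-support[nid].get(s, 0), s))

    for node in atree.tree.preorder_node_iter():
        nid = atree.node_id(node)
        if not node_sets[nid]:
            continue
        if node.is_leaf():
            resolved[nid] = next(iter(node_sets[nid]))
            continue
        cands = node_sets[nid]
        if len(cands) == 1:
            resolved[nid] = next(iter(cands))
            continue
        if node is not root and atree.node_id(node.parent_node) in resolved:
            parent_state = resolved[atree.node_id(node.parent_node)]
            if parent_state in cands:
                resolved[nid] = parent_state
                continue
        if node is root and tdrl_tiebreak and len(cands) == 2:
            s1, s2 = sorted(cands)
            if support[nid].get(s1) == support[nid].get(s2):
                rep1, rep2 = atree.representative(s1), atree.representative(s2)
                d = ancestral_direction(rep1, rep2)
                if d.direction == "forward":
                    resolved[nid] = s1
                    atree.notes.append(
                        f"root tie {s1}/{s2} broken toward {s1} by TDRL polarity"
                    )
                    continue
                if d.direction == "reverse":
                    resolved[nid] = s2
                    atree.notes.append(
                        f"root tie {s1}/{s2} broken toward {s2} by TDRL polarity"
                    )
                    continue
        resolved[nid] = pick(nid, cands)

    atree.node_states = node_sets
    atree.resolved = resolved
    atree.parsimony_score = score
    return atree


def annotate_branch_changes(
    atree: AnnotatedTree,
    max_steps: int = 3,
    reference: SignedGeneOrder = PANGO,
    scenario_cache: Optional[dict] = None,
    all_minimal: bool = True,
) -> AnnotatedTree:
    """Attribute gene-order transitions to branches.

    A branch carries a change iff parent and child resolved states differ;
    it is annotated with the minimal-scenario step count, the preferred
    scenario, and the genes newly repositioned relative to the reference.
    ``all_minimal=False`` reconstructs a single witness scenario per
    transition (faster; step counts are identical either way).
    """
    if not atree.resolved:
        raise ValueError("run ancestral_states first")
    cache: dict = scenario_cache if scenario_cache is not None else {}
    changes: dict[str, BranchChange] = {}
    for node in atree.tree.preorder_node_iter():
        if node is atree.tree.seed_node:
            continue
        nid = atree.node_id(node)
        pid = atree.node_id(node.parent_node)
        if nid not in atree.resolved or pid not in atree.resolved:
            continue
        s, t = atree.resolved[pid], atree.resolved[nid]
        if s == t:
            continue
        key = (s, t)
        if key not in cache:
            cache[key] = infer_scenarios(
                atree.representative(s),
                atree.representative(t),
                max_steps=max_steps,
                all_minimal=all_minimal,
            )
        inf: ScenarioInference = cache[key]
        flags_parent = reposition_score(atree.representative(s), reference).flags
        flags_child = reposition_score(atree.representative(t), reference).flags
        moved = tuple(
            sorted(g for g in flags_child if flags_child[g] and not flags_parent[g])
        )
        changes[nid] = BranchChange(
            parent=pid,
            child=nid,
            source_class=s,
            target_class=t,
            steps=inf.min_steps,
            preferred_scenario=str(inf.preferred) if inf.preferred else "",
            genes_moved=moved,
            exceeded_bound=inf.exceeded_bound,
        )
    atree.branch_changes = changes
    return atree


def scan_hotspot_clades(
    tree: dendropy.Tree,
    node_id: Callable[[dendropy.Node], str],
    state_of: Callable[[str], Optional[str]],
    min_derived_fraction: float = 0.5,
) -> list[tuple[str, tuple[str, ...], frozenset[str], str]]:
    """Maximal clades with >= 2 distinct derived classes at high density.

    A clade's ancestral reference is the state *entering* it (its stem:
    the parent node's state; the root uses its own), so a two-tip clade
    with two different derived orders still reads as doubly derived.
    Derived-tip density must strictly exceed ``min_derived_fraction``.
    ``state_of`` maps node ids (tips and internals) to class ids or None
    for excluded.  Shared between the inference path (reconstructed
    states) and simulation ground truth (planted states): the definition
    is one and the same; only the states differ.
    """
    found: list[tuple[str, tuple[str, ...], frozenset[str], str]] = []
    skip: set[int] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or id(node) in skip:
            continue
        nid = node_id(node)
        stem = node.parent_node
        anc = state_of(node_id(stem)) if stem is not None else state_of(nid)
        if anc is None:
            continue
        tips = [
            node_id(t) for t in node.leaf_iter() if state_of(node_id(t)) is not None
        ]
        if len(tips) < 2:
            continue
        tip_classes = [state_of(t) for t in tips]
        derived = frozenset(c for c in tip_classes if c != anc)
        n_derived_tips = sum(1 for c in tip_classes if c != anc)
        if len(derived) >= 2 and n_derived_tips / len(tips) > min_derived_fraction:
            found.append((nid, tuple(tips), derived, anc))
            for d in node.preorder_iter():
                skip.add(id(d))
    return found


def find_hotspots(
    atree: AnnotatedTree, min_derived_fraction: float = 0.5
) -> list[HotspotClade]:
    """Flag maximal clades of closely related species with dissimilar GOs.

    A hotspot clade carries at least two distinct gene-order classes that
    differ from each other and from the state entering the clade (its
    stem's reconstructed state), and strictly more than
    ``min_derived_fraction`` of its informative tips deviate from that
    state.  Returned in preorder; no flagged clade contains another.
    """
    if not atree.resolved:
        raise ValueError("run ancestral_states first")

    def state_of(nid: str) -> Optional[str]:
        s = atree.resolved.get(nid)
        return None if s in (None, EXCLUDED) else s

    hits = scan_hotspot_clades(
        atree.tree, atree.node_id, state_of, min_derived_fraction
    )
    atree.hotspots = [
        HotspotClade(root_node=n, tips=t, unique_GOs=d, ancestral_GO=a)
        for n, t, d, a in hits
    ]
    return atree.hotspots
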