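"""The end-to-end comparative study as a model/results pair.

:class:`RearrangementStudy` is built from data — parsed genome records,
an optional rooted tree, optional species grouping — plus the analysis
settings (reference order, step bound, scoring unit).  Its :meth:`fit`
runs extraction bookkeeping, deduplication into gene-order classes,
repositioned-gene scoring, pairwise comparison against the reference
(common intervals, minimal scenarios, TDRL polarity, complexity
verdicts), and — when a tree is supplied — ancestral-state
reconstruction, branch-change annotation and hotspot detection.  The
returned :class:`StudyResults` carries every table, prints a
``summary()``, writes a reproducible output directory, and plots the
per-gene reposition counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .genbank import GenomeRecordReport, read_genbank
from .orders import (
    PANGO,
    GeneOrderClass,
    SignedGeneOrder,
    dedupe_gene_orders,
    write_gene_order_tsv,
)
from .phylo import (
    AnnotatedTree,
    HotspotClade,
    ancestral_states,
    annotate_branch_changes,
    attach_states,
    find_hotspots,
    normalize_label,
)
from .scenarios import (
    ancestral_direction,
    common_intervals,
    infer_scenarios,
)
from .scoring import (
    ComplexityVerdict,
    RepositionScore,
    aggregate_reposition_counts,
    classify_transition,
    reposition_score,
)

__all__ = ["RearrangementStudy", "StudyResults"]


class RearrangementStudy:
    """Comparative gene-order analysis over a set of mitochondrial genomes.

    Parameters
    ----------
    reports : parsed genome records (accepted and rejected)
    tree : rooted tree (dendropy Tree, newick string or path), optional
    grouping : species -> group label (e.g. lineage membership), optional
    reference : the comparison order; defaults to the Pancrustacean pattern
    max_steps : scenario search bound (default 3)
    scoring_unit : "per_GO" (each unique order once) or "per_species"
    min_derived_fraction : hotspot density threshold
    all_minimal : enumerate all minimal scenarios (vs one witness each)
    """

    def __init__(
        self,
        reports: Sequence[GenomeRecordReport],
        tree=None,
        grouping: Optional[Mapping[str, str]] = None,
        reference: SignedGeneOrder = PANGO,
        max_steps: int = 3,
        scoring_unit: str = "per_GO",
        min_derived_fraction: float = 0.5,
        all_minimal: bool = True,
    ) -> None:
        self.reports = list(reports)
        self.tree = tree
        self.grouping = dict(grouping) if grouping else None
        self.reference = reference
        self.max_steps = max_steps
        self.scoring_unit = scoring_unit
        self.min_derived_fraction = min_derived_fraction
        self.all_minimal = all_minimal

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_genbank(cls, genomes_path, tree=None, metadata=None, **kwargs):
        """Build from a GenBank flat file (+ optional newick + metadata TSV).

        The metadata table needs ``species`` and ``group`` columns
        (tab-separated, ``#`` comments ignored).
        """
        reports = read_genbank(genomes_path)
        grouping = _read_metadata(metadata) if metadata is not None else None
        return cls(reports, tree=tree, grouping=grouping, **kwargs)

    @classmethod
    def from_simulation(cls, history, **kwargs):
        """Build directly from a planted simulation history."""
        reports = [
            GenomeRecordReport(
                accession=history.accessions[sp],
                species=sp,
                accepted=True,
                order=order,
            )
            for sp, order in sorted(history.tip_orders.items())
        ]
        return cls(
            reports, tree=history.tree, grouping=dict(history.groups), **kwargs
        )

    # -- fitting --------------------------------------------------------
    def fit(self) -> "StudyResults":
        accepted = [r for r in self.reports if r.accepted]
        if not accepted:
            raise ValueError("no accepted genome records to analyse")
        classes, assignment = dedupe_gene_orders(
            [(r.species_id, r.order) for r in accepted]
        )
        class_map = {c.class_id: c for c in classes}

        scores = {
            c.class_id: reposition_score(c.representative, self.reference)
            for c in classes
        }

        member_grouping = None
        if self.grouping is not None:
            norm = {normalize_label(k): v for k, v in self.grouping.items()}
            member_grouping = {}
            missing = []
            for c in classes:
                for sp in c.members:
                    g = norm.get(normalize_label(sp))
                    if g is None:
                        missing.append(sp)
                    else:
                        member_grouping[sp] = g
            if missing:
                raise KeyError(
                    "species missing from grouping: " + ", ".join(sorted(missing))
                )
        counts = aggregate_reposition_counts(
            [(c, scores[c.class_id]) for c in classes],
            grouping=member_grouping,
            unit=self.scoring_unit,
        )

        cache: dict = {}
        comparisons = []
        verdicts: dict[str, ComplexityVerdict] = {}
        for c in classes:
            ci = common_intervals(self.reference, c.representative)
            inf = infer_scenarios(
                self.reference,
                c.representative,
                max_steps=self.max_steps,
                all_minimal=self.all_minimal,
            )
            cache[("__ref__", c.class_id)] = inf
            verdict = classify_transition(inf)
            verdicts[c.class_id] = verdict
            direction = ancestral_direction(
                self.reference, c.representative, self.max_steps
            )
            comparisons.append(
                {
                    "class_id": c.class_id,
                    "n_members": len(c.members),
                    "nsci": ci.nsci,
                    "min_steps": inf.min_steps,
                    "n_minimal_scenarios": len(inf.scenarios),
                    "scenarios_truncated": inf.truncated,
                    "preferred_scenario": str(inf.preferred) if inf.preferred else "",
                    "reposition_count": scores[c.class_id].count,
                    "flagged_genes": ",".join(scores[c.class_id].flagged),
                    "verdict": verdicts[c.class_id].verdict,
                    "criteria": ",".join(sorted(verdicts[c.class_id].triggered)),
                    "verdict_stable": verdicts[c.class_id].stable,
                    "tdrl_direction": direction.direction,
                }
            )
        comparison_table = pd.DataFrame(comparisons)

        atree: Optional[AnnotatedTree] = None
        hotspots: list[HotspotClade] = []
        if self.tree is not None:
            atree = attach_states(self.tree, assignment, class_map)
            ancestral_states(atree)
            annotate_branch_changes(
                atree,
                max_steps=self.max_steps,
                reference=self.reference,
                all_minimal=self.all_minimal,
            )
            hotspots = find_hotspots(atree, self.min_derived_fraction)

        return StudyResults(
            model=self,
            reports=self.reports,
            classes=classes,
            assignment=assignment,
            scores=scores,
            counts=counts,
            comparisons=comparison_table,
            verdicts=verdicts,
            tree=atree,
            hotspots=hotspots,
        )

    def config_dict(self) -> dict:
        return {
            "reference": str(self.reference),
            "max_steps": self.max_steps,
            "scoring_unit": self.scoring_unit,
            "min_derived_fraction": self.min_derived_fraction,
            "all_minimal": self.all_minimal,
            "n_records": len(self.reports),
        }


@dataclass
class StudyResults:
    """Fitted tables and annotations of one comparative study."""

    model: RearrangementStudy
    reports: list[GenomeRecordReport]
    classes: list[GeneOrderClass]
    assignment: dict[str, str]
    scores: dict[str, RepositionScore]
    counts: pd.DataFrame
    comparisons: pd.DataFrame
    verdicts: dict[str, ComplexityVerdict]
    tree: Optional[AnnotatedTree] = None
    hotspots: list[HotspotClade] = field(default_factory=list)

    # -- headline quantities -------------------------------------------
    @property
    def n_accepted(self) -> int:
        return sum(1 for r in self.reports if r.accepted)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def most_repositioned_gene(self) -> tuple[str, int]:
        totals = self.counts.groupby("gene")["count"].sum()
        gene = totals.sort_values(ascending=False, kind="stable").index[0]
        return str(gene), int(totals[gene])

    def max_min_steps(self) -> Optional[int]:
        vals = self.comparisons["min_steps"].dropna()
        return int(vals.max()) if len(vals) else None

    def root_state(self) -> Optional[str]:
        if self.tree is None:
            return None
        return self.tree.resolved.get(self.tree.node_id(self.tree.tree.seed_node))

    def n_complex(self) -> int:
        return sum(
            1
            for cid, v in self.verdicts.items()
            if v.verdict == "complex" and cid != "GO 1"
        )

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Mitochondrial gene-order rearrangement study")
        w("=" * 44)
        w(f"genomes analysed      {len(self.reports)}")
        w(f"  accepted            {self.n_accepted}")
        w(f"  rejected            {len(self.reports) - self.n_accepted}")
        w(f"gene-order classes    {self.n_classes}")
        gene, cnt = self.most_repositioned_gene()
        unit = self.counts.attrs.get("unit", "per_GO")
        w(f"most repositioned     {gene} ({cnt} {unit.replace('per_', '')}(s))")
        steps = self.max_min_steps()
        w(f"max scenario steps    {steps if steps is not None else '>' + str(self.model.max_steps)}")
        w(f"complex transitions   {self.n_complex()} of {max(self.n_classes - 1, 0)} derived classes")
        if self.tree is not None:
            w(f"root state            {self.root_state()}")
            w(f"parsimony score       {self.tree.parsimony_score}")
            w(f"hotspot clades        {len(self.hotspots)}")
            for h in self.hotspots:
                w(
                    f"  {h.root_node}: {len(h.tips)} tips, "
                    f"derived {{{', '.join(sorted(h.unique_GOs))}}} "
                    f"from {h.ancestral_GO}"
                )
        return "\n".join(lines)

    def plot_reposition_counts(self, path=None):
        """Bar chart of per-gene reposition counts by group (headless)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pivot = self.counts.pivot(index="gene", columns="group", values="count")
        fig, ax = plt.subplots(figsize=(8, 4))
        pivot.plot.bar(ax=ax)
        ax.set_ylabel(
            f"reposition count ({self.counts.attrs.get('unit', 'per_GO')})"
        )
        ax.set_xlabel("gene")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig

    # -- persistence ----------------------------------------------------
    def to_directory(self, outdir) -> None:
        """Write all tables (deterministically) to ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        write_gene_order_tsv(self.reports, out / "gene_orders.tsv")

        with open(out / "classes.tsv", "w", encoding="utf-8") as fh:
            fh.write("# mitorder gene-order classes, schema v1\n")
            fh.write("class_id\tn_members\trepresentative\tmembers\n")
            for c in self.classes:
                fh.write(
                    f"{c.class_id}\t{len(c.members)}\t{c.representative}\t"
                    f"{';'.join(c.members)}\n"
                )

        with open(out / "scores.tsv", "w", encoding="utf-8") as fh:
            fh.write("# mitorder reposition scores vs reference, schema v1\n")
            fh.write("class_id\tcount\tflagged_genes\tblocks\n")
            for c in self.classes:
                s = self.scores[c.class_id]
                blocks = ";".join("-".join(b) for b in s.blocks)
                fh.write(
                    f"{c.class_id}\t{s.count}\t{','.join(s.flagged)}\t{blocks}\n"
                )

        counts = self.counts.copy()
        counts.insert(2, "unit", self.counts.attrs.get("unit", "per_GO"))
        with open(out / "reposition_counts.tsv", "w", encoding="utf-8") as fh:
            fh.write("# mitorder per-gene reposition counts, schema v1\n")
            counts.to_csv(fh, sep="\t", index=False)

        with open(out / "comparisons.tsv", "w", encoding="utf-8") as fh:
            fh.write("# mitorder pairwise comparison vs reference, schema v1\n")
            self.comparisons.to_csv(fh, sep="\t", index=False)

        if self.tree is not None:
            with open(out / "annotated_tree.nwk", "w", encoding="utf-8") as fh:
                fh.write(self.tree.to_annotated_newick())
            with open(out / "branch_changes.tsv", "w", encoding="utf-8") as fh:
                fh.write("# mitorder branch changes, schema v1\n")
                fh.write(
                    "parent\tchild\tsource_GO\ttarget_GO\tsteps\t"
                    "preferred_scenario\tgenes_moved\n"
                )
                for nid in sorted(self.tree.branch_changes):
                    bc = self.tree.branch_changes[nid]
                    steps = bc.steps if bc.steps is not None else f">{self.model.max_steps}"
                    fh.write(
                        f"{bc.parent}\t{bc.child}\t{bc.source_class}\t"
                        f"{bc.target_class}\t{steps}\t{bc.preferred_scenario}\t"
                        f"{','.join(bc.genes_moved)}\n"
                    )
            with open(out / "hotspots.tsv", "w", encoding="utf-8") as fh:
                fh.write("# mitorder hotspot clades, schema v1\n")
                fh.write("root_node\tn_tips\tderived_GOs\tancestral_GO\ttips\n")
                for h in self.hotspots:
                    fh.write(
                        f"{h.root_node}\t{len(h.tips)}\t"
                        f"{','.join(sorted(h.unique_GOs))}\t{h.ancestral_GO}\t"
                        f"{';'.join(h.tips)}\n"
                    )

        config = self.model.config_dict()
        config_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16]
        meta = {
            "package": "mitorder",
            "version": __version__,
            "config": config,
            "config_hash": config_hash,
        }
        with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _read_metadata(path) -> dict[str, str]:
    grouping = {}
    with open(path, encoding="utf-8") as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if "species" not in header or "group" not in header:
                    raise ValueError(
                        "metadata table needs 'species' and 'group' columns"
                    )
                continue
            row = dict(zip(header, cells))
            grouping[row["species"]] = row["group"]
    return grouping
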