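"""Extraction of signed gene orders from annotated GenBank records.

Only CDS features matter: the 13 protein-coding genes are identified via
the synonym table from the ``gene`` (then ``product``) qualifiers, ordered
by start coordinate around the circle, and signed by coding strand.
rRNA, tRNA and control-region features are skipped — their frequent loss
and duplication is exactly why the analysis restricts itself to the
protein-coding complement.  A record is accepted only when it yields
exactly one usable copy of every gene; duplicated annotations collapse to
the longest copy not flagged as a pseudogene (tie: earliest start, with a
warning), mirroring how genomes with duplicated/fragmented genes are kept
in comparative datasets rather than discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .genes import GENES, UnknownGeneError, resolve_gene_name
from .orders import SignedGene, SignedGeneOrder

__all__ = [
    "GenomeRecordReport",
    "GenBankParseError",
    "parse_genbank_record",
    "read_genbank",
]

logger = logging.getLogger(__name__)


class GenBankParseError(ValueError):
    """Malformed GenBank input (wraps the parser's complaint and location)."""


@dataclass
class GenomeRecordReport:
    """Outcome of gene-order extraction from one genome record."""

    accession: str
    species: str
    accepted: bool
    order: Optional[SignedGeneOrder] = None
    rejection_reason: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted and self.order is None:
            raise ValueError("accepted report must carry an order")
        if not self.accepted and not self.rejection_reason:
            raise ValueError("rejected report must carry a reason")

    @property
    def species_id(self) -> str:
        """Organism plus accession, disambiguating conspecific genomes."""
        return f"{self.species.replace(' ', '_')}|{self.accession}"


def _feature_name(feature) -> Optional[str]:
    for key in ("gene", "product"):
        for value in feature.qualifiers.get(key, []):
            try:
                return resolve_gene_name(value)
            except UnknownGeneError:
                continue
    return None


def _is_pseudo(feature) -> bool:
    return "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers


def parse_genbank_record(record: SeqRecord) -> GenomeRecordReport:
    """Extract the signed 13-gene order from one annotated record."""
    accession = record.id or record.name or "?"
    species = record.annotations.get("organism", "") or _source_organism(record)

    cds = [f for f in record.features if f.type == "CDS"]
    if not cds:
        return GenomeRecordReport(
            accession, species, accepted=False,
            rejection_reason="no CDS features",
        )

    candidates: dict[str, list] = {}
    warnings: list[str] = []
    unassigned = 0
    for f in cds:
        label = _feature_name(f)
        if label is None:
            unassigned += 1
            continue
        candidates.setdefault(label, []).append(f)
    if unassigned:
        warnings.append(f"{unassigned} CDS feature(s) with unrecognized names skipped")

    chosen: dict[str, object] = {}
    for label, feats in candidates.items():
        usable = [f for f in feats if not _is_pseudo(f)]
        if not usable:
            continue  # only pseudogene copies: treat as missing
        if len(feats) > 1:
            usable.sort(key=lambda f: (-(len(f.location)), int(f.location.start)))
            warnings.append(
                f"duplicate {label}: kept longest non-pseudogene copy at "
                f"{int(usable[0].location.start) + 1} of {len(feats)} annotations"
            )
        chosen[label] = usable[0]

    missing = sorted(set(GENES) - set(chosen))
    if missing:
        return GenomeRecordReport(
            accession, species, accepted=False,
            rejection_reason=f"missing: {', '.join(missing)}",
            warnings=warnings,
        )

    bad_strand = sorted(
        l for l, f in chosen.items() if f.location.strand not in (1, -1)
    )
    if bad_strand:
        return GenomeRecordReport(
            accession, species, accepted=False,
            rejection_reason=f"no strand information: {', '.join(bad_strand)}",
            warnings=warnings,
        )

    placed = sorted(chosen.items(), key=lambda kv: int(kv[1].location.start))
    order = SignedGeneOrder(
        tuple(SignedGene(l, int(f.location.strand)) for l, f in placed)
    )
    for w in warnings:
        logger.warning("%s: %s", accession, w)
    return GenomeRecordReport(
        accession, species, accepted=True, order=order, warnings=warnings
    )


def _source_organism(record: SeqRecord) -> str:
    for f in record.features:
        if f.type == "source":
            vals = f.qualifiers.get("organism", [])
            if vals:
                return vals[0]
    return "unknown organism"


def read_genbank(path) -> list[GenomeRecordReport]:
    """Parse a single- or multi-record GenBank flat file into reports."""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    if not records:
        with open(path, encoding="utf-8", errors="replace") as fh:
            first = next((l.rstrip() for l in fh if l.strip()), "")
        if first and not first.startswith("LOCUS"):
            raise GenBankParseError(
                f"{path}: not GenBank format (first line: {first!r})"
            )
    return [parse_genbank_record(r) for r in records]


def accepted_orders(reports: Iterable[GenomeRecordReport]) -> list[tuple[str, SignedGeneOrder]]:
    """(species_id, order) pairs for the accepted records."""
    return [(r.species_id, r.order) for r in reports if r.accepted]
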