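"""Signed circular gene orders and their deduplication into order classes.

A mitochondrial genome is modelled as a circular arrangement of the 13
protein-coding genes, each carrying a sign for its coding strand.  Two
genomes have "the same gene order" when one circular arrangement can be
rotated — or read from the opposite strand (reversed with all signs
flipped) — into the other.  All comparisons therefore go through a
canonical linearization: the order is rotated to start at cox1, after first
reverse-complementing the whole arrangement if cox1 sits on the minus
strand.  The canonical form is what gets hashed, compared, serialized and
deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .genes import GENES, GENE_INDEX, PANGO_SIGNED

__all__ = [
    "SignedGene",
    "SignedGeneOrder",
    "GeneOrderClass",
    "PANGO",
    "canonicalize",
    "orders_equal",
    "dedupe_gene_orders",
    "write_gene_order_tsv",
]


@dataclass(frozen=True, order=True)
class SignedGene:
    """One gene with its coding strand (+1 or -1)."""

    label: str
    strand: int

    def __post_init__(self) -> None:
        if self.label not in GENE_INDEX:
            raise ValueError(f"unknown gene label {self.label!r}")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")

    def flipped(self) -> "SignedGene":
        return SignedGene(self.label, -self.strand)

    def __str__(self) -> str:
        return self.label if self.strand > 0 else f"-{self.label}"


def _parse_signed_token(token: str) -> SignedGene:
    token = token.strip()
    if token.startswith("-"):
        return SignedGene(token[1:], -1)
    return SignedGene(token.lstrip("+"), +1)


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular signed arrangement of the 13 protein-coding genes.

    ``genes`` stores the canonical linearization (cox1 first, on the +
    strand); the constructor canonicalizes whatever rotation/reading it is
    given, so construction is idempotent and two orders related by rotation
    or whole-order reverse-complement compare equal.
    """

    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        labels = [g.label for g in genes]
        if sorted(labels) != sorted(GENES):
            missing = sorted(set(GENES) - set(labels))
            extra = sorted(set(labels) - set(GENES))
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(
                "an order must contain each of the 13 genes exactly once "
                f"(missing={missing}, unknown={extra}, duplicated={dupes})"
            )
        object.__setattr__(self, "genes", _canonical_tuple(genes))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "SignedGeneOrder":
        return cls(tuple(SignedGene(l, s) for l, s in pairs))

    @classmethod
    def from_string(cls, text: str, sep: str = ",") -> "SignedGeneOrder":
        """Parse e.g. ``"cox1,cox2,atp8,...,-nad5,..."``."""
        return cls(tuple(_parse_signed_token(t) for t in text.split(sep)))

    # -- views ----------------------------------------------------------
    @property
    def canonical_form(self) -> tuple[SignedGene, ...]:
        return self.genes

    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.genes)

    def strand_of(self, label: str) -> int:
        for g in self.genes:
            if g.label == label:
                return g.strand
        raise KeyError(label)

    def rotated(self, k: int) -> "SignedGeneOrder":
        """The same circular molecule linearized from another start (a no-op
        after canonicalization; useful for constructing test inputs)."""
        g = self.genes
        return SignedGeneOrder(g[k % 13 :] + g[: k % 13])

    def reverse_complement(self) -> "SignedGeneOrder":
        """The same molecule read from the other strand (also a no-op after
        canonicalization)."""
        return SignedGeneOrder(tuple(g.flipped() for g in reversed(self.genes)))

    def __str__(self) -> str:
        return ",".join(str(g) for g in self.genes)

    def __iter__(self) -> Iterator[SignedGene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return 13


def _canonical_tuple(genes: Sequence[SignedGene]) -> tuple[SignedGene, ...]:
    genes = tuple(genes)
    i = next(k for k, g in enumerate(genes) if g.label == "cox1")
    if genes[i].strand < 0:
        genes = tuple(g.flipped() for g in reversed(genes))
        i = len(genes) - 1 - i
    return genes[i:] + genes[:i]


#: The Pancrustacean ground pattern as a :class:`SignedGeneOrder`.
PANGO = SignedGeneOrder.from_pairs(PANGO_SIGNED)


def canonicalize(order: SignedGeneOrder) -> SignedGeneOrder:
    """Return the canonical linearization (cox1 first, + strand).

    Orders canonicalize on construction, so this is the identity on any
    existing :class:`SignedGeneOrder`; it exists as the named operation and
    for symmetry with raw gene tuples.
    """
    return SignedGeneOrder(order.genes)


def orders_equal(a: SignedGeneOrder, b: SignedGeneOrder) -> bool:
    """True iff the two circular orders have identical canonical forms."""
    return a.canonical_form == b.canonical_form


@dataclass
class GeneOrderClass:
    """One unique gene-order pattern ("GO k") and the genomes carrying it."""

    class_id: str
    representative: SignedGeneOrder
    members: list[str] = field(default_factory=list)

    def __contains__(self, species: str) -> bool:
        return species in self.members


def dedupe_gene_orders(
    orders: Sequence[tuple[str, SignedGeneOrder]],
) -> tuple[list[GeneOrderClass], dict[str, str]]:
    """Collapse (species, order) pairs into unique gene-order classes.

    Class ids are assigned in first-encounter order of the input, except
    that the class matching the Pancrustacean pattern is always "GO 1"
    (when present), mirroring the convention that GO 1 is the reference.

    Returns the class list and a species -> class_id map.
    """
    by_form: dict[tuple[SignedGene, ...], GeneOrderClass] = {}
    encounter: list[GeneOrderClass] = []
    for species, order in orders:
        cls = by_form.get(order.canonical_form)
        if cls is None:
            cls = GeneOrderClass(class_id="", representative=order)
            by_form[order.canonical_form] = cls
            encounter.append(cls)
        if species in cls.members:
            raise ValueError(f"duplicate species identifier {species!r}")
        cls.members.append(species)

    pango_cls = by_form.get(PANGO.canonical_form)
    ordered: list[GeneOrderClass] = []
    if pango_cls is not None:
        ordered.append(pango_cls)
    ordered.extend(c for c in encounter if c is not pango_cls)
    for k, cls in enumerate(ordered, start=1):
        cls.class_id = f"GO {k}"

    assignment = {sp: cls.class_id for cls in ordered for sp in cls.members}
    return ordered, assignment


def read_gene_order_tsv(path) -> list[tuple[str, str, bool, str, Optional[SignedGeneOrder]]]:
    """Read rows written by :func:`write_gene_order_tsv`.

    Returns (accession, species, accepted, reason, order) tuples.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("accession\t"):
                continue
            acc, species, accepted, reason, order_s = line.split("\t")
            order = SignedGeneOrder.from_string(order_s) if order_s else None
            out.append((acc, species, accepted == "1", reason, order))
    return out


def write_gene_order_tsv(reports, path) -> None:
    """Write one row per genome: accession, species, accepted flag,
    rejection reason, canonical order as comma-separated signed labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mitorder gene-order table, schema v1\n")
        fh.write("accession\tspecies\taccepted\trejection_reason\torder\n")
        for r in reports:
            order = str(r.order) if r.order is not None else ""
            fh.write(
                f"{r.accession}\t{r.species}\t{int(r.accepted)}\t"
                f"{r.rejection_reason or ''}\t{order}\n"
            )
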