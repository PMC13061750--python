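"""The closed set of 13 mitochondrial protein-coding gene labels.

Animal mitochondrial genomes carry 13 protein-coding genes (two ATP synthase
subunits, three cytochrome c oxidase subunits, cytochrome b, and seven NADH
dehydrogenase subunits).  The whole package works on circular signed
arrangements of exactly these 13 labels; ribosomal RNAs, tRNAs and the
control region are deliberately outside the model, because their frequent
loss and duplication would break one-to-one comparability between genomes.

GenBank annotation dialects name these genes inconsistently (``COI``,
``COX1``, ``cox1``, ``cytochrome c oxidase subunit I`` ...), so label
resolution goes through a versioned synonym table shipped with the package.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

__all__ = [
    "GENES",
    "GENE_INDEX",
    "PANGO_SIGNED",
    "resolve_gene_name",
    "UnknownGeneError",
]

#: The 13 protein-coding gene labels, alphabetical.
GENES: tuple[str, ...] = (
    "atp6",
    "atp8",
    "cox1",
    "cox2",
    "cox3",
    "cytb",
    "nad1",
    "nad2",
    "nad3",
    "nad4",
    "nad4l",
    "nad5",
    "nad6",
)

GENE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GENES)}

#: The Pancrustacean ground pattern (PanGO): the ancestral arrangement shared
#: by insects and many crustaceans, transcribed from the Drosophila yakuba
#: arrangement of Boore (1999), restricted to the 13 protein-coding genes and
#: linearized at cox1 on the majority (+) strand.  Signs give the coding
#: strand of each gene.
PANGO_SIGNED: tuple[tuple[str, int], ...] = (
    ("cox1", +1),
    ("cox2", +1),
    ("atp8", +1),
    ("atp6", +1),
    ("cox3", +1),
    ("nad3", +1),
    ("nad5", -1),
    ("nad4", -1),
    ("nad4l", -1),
    ("nad6", +1),
    ("cytb", +1),
    ("nad1", -1),
    ("nad2", +1),
)


class UnknownGeneError(KeyError):
    """Raised when a gene name cannot be resolved to one of the 13 labels."""


_NORM_RE = re.compile(r"[\s\-_]+")


def _normalize(name: str) -> str:
    return _NORM_RE.sub("_", name.strip().lower()).strip("_")


@lru_cache(maxsize=1)
def _synonym_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = (
        resources.files("mitorder")
        .joinpath("data/gene_synonyms.tsv")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        synonym, canonical = line.split("\t")
        if canonical not in GENE_INDEX:
            raise ValueError(f"synonym table maps to unknown label {canonical!r}")
        table[_normalize(synonym)] = canonical
    return table


def resolve_gene_name(name: str) -> str:
    """Resolve a GenBank gene/product name to one of the 13 canonical labels.

    Raises :class:`UnknownGeneError` for names outside the closed set
    (e.g. tRNAs, rRNAs, ORFs), which callers typically skip.
    """
    canonical = _synonym_table().get(_normalize(name))
    if canonical is None:
        raise UnknownGeneError(name)
    return canonical
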