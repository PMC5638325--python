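"""Core entity and link vocabulary for the genetic-information ontology.

The ontology relates three classes of biological entities — proteins
(UniProt entries), genes and mRNA sequence records — each identified in
one of five namespaces.  Genes split into GenBank (Entrez) and Ensembl
sub-classes, mRNAs into RefSeq and EMBL sub-classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NAMESPACES = frozenset(
    {"uniprot", "gene_genbank", "gene_ensembl", "mrna_refseq", "mrna_embl"}
)

#: Target levels for network normalization.
LEVEL_PROTEIN = "protein"
LEVEL_GENE = "gene"
LEVELS = (LEVEL_PROTEIN, LEVEL_GENE)

#: Namespace(s) making up each normalization level.  The gene level is
#: Entrez-keyed; Ensembl genes are way-points, never normalization targets.
LEVEL_NAMESPACES = {
    LEVEL_PROTEIN: frozenset({"uniprot"}),
    LEVEL_GENE: frozenset({"gene_genbank"}),
}

#: The permitted cross-reference link kinds, written "<ns_a>-<ns_b>".
#: The first six are the explicit protein/gene/mRNA cross-references; the
#: last two are the indirect bridges (Ensembl gene -> Entrez gene, and
#: EMBL mRNA -> Ensembl gene is expressed through gene_ensembl-mrna_embl,
#: while EMBL mRNA -> RefSeq mRNA has its own kind).
LINK_KINDS = {
    "uniprot-gene_genbank": ("uniprot", "gene_genbank"),
    "uniprot-gene_ensembl": ("uniprot", "gene_ensembl"),
    "uniprot-mrna_refseq": ("uniprot", "mrna_refseq"),
    "uniprot-mrna_embl": ("uniprot", "mrna_embl"),
    "gene_genbank-mrna_refseq": ("gene_genbank", "mrna_refseq"),
    "gene_ensembl-mrna_embl": ("gene_ensembl", "mrna_embl"),
    "gene_ensembl-gene_genbank": ("gene_ensembl", "gene_genbank"),
    "mrna_embl-mrna_refseq": ("mrna_embl", "mrna_refseq"),
}


class ConfigurationError(ValueError):
    """A config file or declared table kind is invalid."""


class InputError(ValueError):
    """An input file violates its declared format contract."""


def strip_version(accession: str) -> str:
    """Strip a trailing numeric version ("NM_000001.2" -> "NM_000001").

    Accession standards keep the stem case-stable while source files mix
    versioned and unversioned forms; matching is on the stem.
    """
    stem, dot, ver = accession.rpartition(".")
    if dot and stem and ver.isdigit():
        return stem
    return accession


@dataclass(frozen=True, order=True)
class EntityRef:
    """A reference to one biological entity in one of the five namespaces."""

    namespace: str
    accession: str
    is_deprecated_alias: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace: {self.namespace!r}")
        if not self.accession:
            raise ValueError("accession must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.namespace, strip_version(self.accession))


def link_kind_for(ns_a: str, ns_b: str) -> str | None:
    """Return the canonical link kind joining two namespaces, if any."""
    for kind, (a, b) in LINK_KINDS.items():
        if {a, b} == {ns_a, ns_b}:
            return kind
    return None
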