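"""Parse primary interaction datasets in their native dialects.

Four PSI-MITAB dialects (BioGRID, IntAct, MINT, DIP) and an HPRD-style
pair of flat files are supported.  Each retained line becomes one
:class:`RawInteractionRecord` carrying the interactors exactly as the
source reported them — the level of genetic reference differs per source
(BioGRID: Entrez gene, IntAct/MINT/DIP: UniProt, HPRD: mRNA) and is never
converted here.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .entities import EntityRef, InputError

logger = logging.getLogger(__name__)

SOURCE_DBS = ("biogrid", "intact", "mint", "dip", "hprd")

HUMAN_TAXID = 9606

#: PSI-MITAB identifier-namespace prefixes mapped onto ontology namespaces.
XREF_NAMESPACES = {
    "uniprotkb": "uniprot",
    "uniprot": "uniprot",
    "entrez gene/locuslink": "gene_genbank",
    "entrezgene/locuslink": "gene_genbank",
    "entrez gene": "gene_genbank",
    "refseq": "mrna_refseq",
    "embl": "mrna_embl",
    "ddbj/embl/genbank": "mrna_embl",
    "ensembl": "gene_ensembl",
}

#: Interactor-identifier precedence per source dialect: the first namespace
#: with a usable token (scanning the primary then the alternative identifier
#: columns) wins.  Each source's native reporting level is first in its list.
DIALECT_ID_PRECEDENCE: dict[str, tuple[str, ...]] = {
    "biogrid": ("gene_genbank", "uniprot", "mrna_refseq"),
    "intact": ("uniprot", "mrna_refseq", "mrna_embl"),
    "mint": ("uniprot", "mrna_refseq", "mrna_embl"),
    "dip": ("uniprot", "mrna_refseq"),
}

_TERM_RE = re.compile(r'\(([^()]*)\)\s*$')
_TAXID_RE = re.compile(r'taxid:(-?\d+)')


class AssociationKind(str, Enum):
    """Classification of a raw record by what its evidence describes."""

    PPI_CANDIDATE = "ppi_candidate"
    PROTEIN_GENE_OR_RNA = "protein_gene_or_rna"
    GENETIC_INTERFERENCE = "genetic_interference"
    DISCARD = "discard"


@dataclass
class RawInteractionRecord:
    """One source-database line, with interactors as originally reported."""

    source_db: str
    interactor_a: EntityRef
    interactor_b: EntityRef
    taxid_a: int
    taxid_b: int
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db: {self.source_db!r}")

    @property
    def interaction_type(self) -> str:
        return self.attributes.get("interaction_type", "")

    @property
    def detection_method(self) -> str:
        return self.attributes.get("detection_method", "")

    @property
    def throughput_or_expansion(self) -> str:
        return self.attributes.get("throughput_or_expansion", "")

    @property
    def publications(self) -> tuple[str, ...]:
        return tuple(self.attributes.get("publications", ()))


@dataclass
class IngestReport:
    """Per-file accounting: parsed, skipped and why."""

    parsed: int = 0
    skipped: int = 0
    reasons: dict[str, int] = field(default_factory=lambda: defaultdict(int))

    def skip(self, reason: str) -> None:
        self.skipped += 1
        self.reasons[reason] += 1
        logger.debug("skipped line: %s", reason)


def _term_name(token: str) -> str:
    """Extract the human-readable term from e.g. psi-mi:"MI:0915"(physical association)."""
    token = token.strip()
    if token in ("", "-"):
        return ""
    m = _TERM_RE.search(token)
    if m:
        return m.group(1).strip().strip('"')
    # bare term or namespace:term without parenthesized name
    _, _, rest = token.rpartition(":")
    return rest.strip().strip('"')


def _parse_xref_tokens(field_value: str) -> list[tuple[str, str]]:
    """Split a pipe-separated identifier field into (namespace, accession)."""
    out: list[tuple[str, str]] = []
    if field_value.strip() in ("", "-"):
        return out
    for token in field_value.split("|"):
        ns, sep, acc = token.partition(":")
        if not sep:
            continue
        ns = ns.strip().casefold()
        acc = acc.strip().strip('"')
        # drop any trailing parenthesized description
        acc = re.sub(r"\(.*\)$", "", acc)
        mapped = XREF_NAMESPACES.get(ns)
        if mapped and acc:
            out.append((mapped, acc))
    return out


def _pick_interactor(
    primary: str, alternatives: str, precedence: tuple[str, ...]
) -> EntityRef | None:
    tokens = _parse_xref_tokens(primary) + _parse_xref_tokens(alternatives)
    for wanted in precedence:
        for ns, acc in tokens:
            if ns == wanted:
                return EntityRef(ns, acc)
    return None


def _parse_taxid(field_value: str) -> int | None:
    m = _TAXID_RE.search(field_value)
    return int(m.group(1)) if m else None


def _parse_publications(field_value: str) -> tuple[str, ...]:
    pubs = []
    for token in field_value.split("|"):
        ns, sep, acc = token.partition(":")
        if sep and ns.strip().casefold() == "pubmed" and acc.strip():
            pubs.append(acc.strip())
    return tuple(dict.fromkeys(pubs))  # de-duplicate, keep order


def read_psimitab(
    path: str | Path, source_db: str, report: IngestReport | None = None
) -> list[RawInteractionRecord]:
    """Read a PSI-MITAB 2.5/2.7-style file for one source database.

    Columns follow the MITAB convention: identifier columns hold
    pipe-separated ``namespace:accession`` tokens, controlled-vocabulary
    columns hold ``psi-mi:"MI:xxxx"(term name)`` tokens.  Column 16, when
    present, carries the expansion method (IntAct/MINT) or the throughput
    label (BioGRID/DIP exports merged from the tab2 variant).  Malformed
    lines are logged and skipped; the report counts them.
    """
    if source_db not in DIALECT_ID_PRECEDENCE:
        raise InputError(f"no PSI-MITAB dialect for source {source_db!r}")
    report = report if report is not None else IngestReport()
    precedence = DIALECT_ID_PRECEDENCE[source_db]
    path = Path(path)
    records: list[RawInteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                report.skip("too_few_columns")
                continue
            ref_a = _pick_interactor(cols[0], cols[2] if len(cols) > 2 else "", precedence)
            ref_b = _pick_interactor(cols[1], cols[3] if len(cols) > 3 else "", precedence)
            if ref_a is None or ref_b is None:
                report.skip("no_usable_identifier")
                continue
            taxid_a = _parse_taxid(cols[9]) if len(cols) > 9 else None
            taxid_b = _parse_taxid(cols[10]) if len(cols) > 10 else None
            if taxid_a is None or taxid_b is None:
                report.skip("missing_taxid")
                continue
            publications = _parse_publications(cols[8]) if len(cols) > 8 else ()
            expansion = _term_name(cols[15]) if len(cols) > 15 else ""
            records.append(
                RawInteractionRecord(
                    source_db=source_db,
                    interactor_a=ref_a,
                    interactor_b=ref_b,
                    taxid_a=taxid_a,
                    taxid_b=taxid_b,
                    attributes={
                        "interaction_type": _term_name(cols[11]),
                        "detection_method": _term_name(cols[6]),
                        "throughput_or_expansion": expansion,
                        "publications": publications,
                        "line_number": lineno,
                    },
                )
            )
            report.parsed += 1
    if not records and report.skipped == 0:
        raise InputError(f"no interaction lines in {path}")
    if not records:
        raise InputError(f"zero parseable lines in {path}")
    return records


def read_hprd(
    binary_path: str | Path,
    id_mapping_path: str | Path,
    report: IngestReport | None = None,
) -> list[RawInteractionRecord]:
    """Read an HPRD-style binary-interaction file plus its identifier map.

    The mapping file gives each hprd ID exactly one nucleotide (mRNA)
    accession — RefSeq or EMBL, told apart by the RefSeq ``NM_/NR_/XM_/XR_``
    prefix; duplicated mappings are an input error.  Interactors therefore
    become mRNA-level references.  Pairs with an unmapped hprd ID are
    dropped and logged.  Taxon is human by construction.
    """
    report = report if report is not None else IngestReport()
    mapping: dict[str, str] = {}
    with open(id_mapping_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise InputError(f"{id_mapping_path}:{lineno}: expected >=2 columns")
            hprd_id, nt_acc = parts[0].strip(), parts[1].strip()
            if hprd_id in mapping and mapping[hprd_id] != nt_acc:
                raise InputError(
                    f"hprd ID {hprd_id} maps to multiple nucleotide accessions"
                )
            mapping[hprd_id] = nt_acc

    def _mrna_ref(acc: str) -> EntityRef:
        ns = (
            "mrna_refseq"
            if re.match(r"^(NM_|NR_|XM_|XR_)", acc)
            else "mrna_embl"
        )
        return EntityRef(ns, acc)

    records: list[RawInteractionRecord] = []
    with open(binary_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                report.skip("too_few_columns")
                continue
            hprd_a, hprd_b, expt_types, pubs = parts[0], parts[1], parts[2], parts[3]
            if hprd_a not in mapping or hprd_b not in mapping:
                report.skip("unmapped_hprd_id")
                continue
            publications = tuple(
                p.strip() for p in re.split(r"[|,]", pubs) if p.strip()
            )
            # each experiment type on a line is a distinct evidence line
            for expt in [t.strip() for t in expt_types.split(";") if t.strip()]:
                records.append(
                    RawInteractionRecord(
                        source_db="hprd",
                        interactor_a=_mrna_ref(mapping[hprd_a]),
                        interactor_b=_mrna_ref(mapping[hprd_b]),
                        taxid_a=HUMAN_TAXID,
                        taxid_b=HUMAN_TAXID,
                        attributes={
                            "interaction_type": "physical association",
                            "detection_method": expt,
                            "throughput_or_expansion": "",
                            "publications": publications,
                            "line_number": lineno,
                        },
                    )
                )
                report.parsed += 1
    return records


def filter_human(records: Iterable[RawInteractionRecord]) -> list[RawInteractionRecord]:
    """Keep records where both interactors are human (taxid 9606)."""
    return [
        r
        for r in records
        if r.taxid_a == HUMAN_TAXID and r.taxid_b == HUMAN_TAXID
    ]


def classify_association(
    record: RawInteractionRecord, cv_config: Mapping[str, Iterable[str]]
) -> AssociationKind:
    """Classify a record by its controlled-vocabulary terms.

    Genetic-interference terms (in either the interaction type or the
    detection method) mark the record for discard from the interaction
    network; protein–gene/RNA experimental systems mark it for the
    cross-checking side store; everything else is a candidate
    protein–protein interaction.
    """
    interference = {t.casefold() for t in cv_config.get("genetic_interference_terms", ())}
    gene_rna = {t.casefold() for t in cv_config.get("protein_gene_rna_terms", ())}
    itype = record.interaction_type.casefold()
    method = record.detection_method.casefold()
    if itype in interference or method in interference:
        return AssociationKind.GENETIC_INTERFERENCE
    if itype in gene_rna or method in gene_rna:
        return AssociationKind.PROTEIN_GENE_OR_RNA
    return AssociationKind.PPI_CANDIDATE


def convert_hprd_terms(
    records: Iterable[RawInteractionRecord],
    conversion: Mapping[str, str],
    default_term: str = "",
) -> list[RawInteractionRecord]:
    """Convert HPRD's non-PSI-MI experiment vocabulary in place.

    Unknown terms fall through to ``default_term`` (empty keeps the
    original term), never to an error.
    """
    folded = {k.casefold(): v for k, v in conversion.items()}
    out = []
    for r in records:
        if r.source_db == "hprd":
            term = r.detection_method
            converted = folded.get(term.casefold())
            if converted is not None:
                r.attributes["detection_method"] = converted
            elif default_term:
                r.attributes["detection_method"] = default_term
        out.append(r)
    return out
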