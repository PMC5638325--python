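"""Build and query the genetic-information ontology graph.

The graph links a fixed reference proteome (the curated human proteome's
UniProt accessions, or any accession list supplied) to the gene and mRNA
records cross-referenced with it.  It is the substrate every primary
interaction dataset is superimposed on and every normalization traverses.

Construction is strictly bottom-up: protein nodes come solely from the
reference proteome, and gene/mRNA nodes enter only when a supplied
cross-reference row connects them (directly or transitively) to a
reference protein.  Rows outside that closure are dropped and counted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .entities import (
    LEVEL_NAMESPACES,
    LINK_KINDS,
    NAMESPACES,
    ConfigurationError,
    EntityRef,
    InputError,
    link_kind_for,
    strip_version,
)

logger = logging.getLogger(__name__)

NodeKey = tuple[str, str]  # (namespace, version-stripped accession)


@dataclass
class CrossrefTable:
    """One typed cross-reference table: rows of (accession_from, accession_to).

    ``link_kind`` declares the namespaces of the two columns; ``provenance``
    names the exported source table for audit.
    """

    link_kind: str
    rows: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.link_kind not in LINK_KINDS:
            raise ConfigurationError(f"unknown link_kind: {self.link_kind!r}")

    @property
    def namespaces(self) -> tuple[str, str]:
        return LINK_KINDS[self.link_kind]


@dataclass
class BuildReport:
    """Accounting of what a graph-building step kept, dropped and inferred."""

    dropped_rows: int = 0
    inferred_edges: int = 0
    updates_applied: int = 0
    obsolete_removed: int = 0
    messages: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.messages.append(msg)
        logger.info(msg)

    def write(self, path: str | Path) -> None:
        lines = [
            f"dropped_rows\t{self.dropped_rows}",
            f"inferred_edges\t{self.inferred_edges}",
            f"updates_applied\t{self.updates_applied}",
            f"obsolete_removed\t{self.obsolete_removed}",
            *self.messages,
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class OntologyNode:
    """Read-only view of one active ontology entry.

    Identity (equality, hashing) is by entity reference; the attribute map
    and alias set are descriptive payload.
    """

    ref: EntityRef
    attributes: Mapping[str, str] = field(compare=False, hash=False, default_factory=dict)
    deprecated_aliases: frozenset[str] = field(compare=False, hash=False, default=frozenset())
    status: str = field(compare=False, default="active")

    @property
    def namespace(self) -> str:
        return self.ref.namespace

    @property
    def accession(self) -> str:
        return self.ref.accession


class OntologyGraph:
    """Typed multigraph of protein/gene/mRNA entities and their links.

    Nodes are keyed by ``(namespace, accession)`` with versions stripped
    from accessions.  Edges carry their declared ``link_kind``, source-table
    provenance and an ``inferred`` flag for bridge-derived links.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()
        self._alias_index: dict[str, set[NodeKey]] = defaultdict(set)
        self.report = BuildReport()

    # -- structure ---------------------------------------------------------

    @property
    def nx_graph(self) -> nx.MultiGraph:
        return self._g

    def __contains__(self, key: NodeKey) -> bool:
        return key in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def node_keys(self, namespace: str | None = None) -> list[NodeKey]:
        keys = list(self._g.nodes)
        if namespace is not None:
            keys = [k for k in keys if k[0] == namespace]
        return sorted(keys)

    def node(self, key: NodeKey) -> OntologyNode:
        data = self._g.nodes[key]
        return OntologyNode(
            ref=EntityRef(key[0], key[1]),
            attributes=dict(data.get("attributes", {})),
            deprecated_aliases=frozenset(data.get("deprecated_aliases", ())),
            status="active",
        )

    def add_node(self, namespace: str, accession: str, **attributes: str) -> NodeKey:
        key = (namespace, strip_version(accession))
        if key not in self._g:
            self._g.add_node(key, attributes={}, deprecated_aliases=set())
        if accession != key[1]:
            # keep the original versioned form for provenance
            self._g.nodes[key]["attributes"].setdefault("versioned_form", accession)
        if attributes:
            self._g.nodes[key]["attributes"].update(attributes)
        return key

    def set_attribute(self, key: NodeKey, name: str, value: str) -> None:
        self._g.nodes[key]["attributes"][name] = value

    def add_edge(
        self,
        key_a: NodeKey,
        key_b: NodeKey,
        link_kind: str,
        provenance: str = "",
        inferred: bool = False,
    ) -> bool:
        """Add one typed edge; returns False when an identical edge exists."""
        if link_kind not in LINK_KINDS:
            raise ConfigurationError(f"unknown link_kind: {link_kind!r}")
        if link_kind_for(key_a[0], key_b[0]) != link_kind:
            raise ConfigurationError(
                f"link_kind {link_kind!r} inconsistent with endpoints "
                f"{key_a[0]!r}/{key_b[0]!r}"
            )
        if self._g.has_edge(key_a, key_b):
            for data in self._g.get_edge_data(key_a, key_b).values():
                if (
                    data["link_kind"] == link_kind
                    and data["provenance"] == provenance
                    and data["inferred"] == inferred
                ):
                    return False
        self._g.add_edge(
            key_a, key_b, link_kind=link_kind, provenance=provenance, inferred=inferred
        )
        return True

    def edges(self) -> Iterator[tuple[NodeKey, NodeKey, dict]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data

    def neighbors(self, key: NodeKey) -> list[NodeKey]:
        return sorted(self._g.neighbors(key))

    def degree(self, key: NodeKey) -> int:
        return self._g.degree(key)

    # -- aliases and resolution -------------------------------------------

    def add_alias(self, key: NodeKey, alias: str) -> None:
        alias = strip_version(alias)
        if alias == key[1]:
            raise ValueError("a node cannot alias its own accession")
        self._g.nodes[key]["deprecated_aliases"].add(alias)
        self._alias_index[alias].add(key)

    @property
    def alias_index(self) -> Mapping[str, set[NodeKey]]:
        return self._alias_index

    def resolve_accession(self, namespace: str, accession: str) -> set[NodeKey]:
        """Resolve an accession within one namespace, via key or alias only.

        This is the strict resolution used when superimposing primary
        records; attribute (symbol) matching is deliberately excluded.
        """
        stem = strip_version(accession)
        key = (namespace, stem)
        if key in self._g:
            return {key}
        return {k for k in self._alias_index.get(stem, ()) if k[0] == namespace}

    def resolve(
        self, token: str, namespace_hint: str | None = None
    ) -> set[NodeKey]:
        """Resolve a token to active nodes by accession, alias or attribute.

        Accessions and aliases match exactly (case-sensitive, versions
        stripped); stored attribute values such as gene symbols match
        case-insensitively.
        """
        if not token:
            raise ValueError("token must be non-empty")
        if namespace_hint is not None and namespace_hint not in NAMESPACES:
            raise ConfigurationError(f"unknown namespace hint: {namespace_hint!r}")
        stem = strip_version(token)
        hits: set[NodeKey] = set()
        for ns in NAMESPACES:
            if (ns, stem) in self._g:
                hits.add((ns, stem))
        hits |= self._alias_index.get(stem, set())
        folded = token.casefold()
        for key, data in self._g.nodes(data=True):
            if any(str(v).casefold() == folded for v in data["attributes"].values()):
                hits.add(key)
        if namespace_hint is not None:
            hits = {k for k in hits if k[0] == namespace_hint}
        return hits

    # -- integrity ---------------------------------------------------------

    def check_closure(self) -> None:
        """Assert every non-protein node connects to >=1 protein node."""
        protein_keys = {k for k in self._g.nodes if k[0] == "uniprot"}
        for comp in nx.connected_components(self._g):
            if not (comp & protein_keys):
                stray = sorted(comp)[0]
                raise AssertionError(
                    f"node {stray} not connected to any protein node"
                )

    # -- serialization -----------------------------------------------------

    def dump(self, node_path: str | Path, edge_path: str | Path) -> None:
        with open(node_path, "w") as fh:
            fh.write("namespace\taccession\taliases\tattributes\n")
            for ns, acc in sorted(self._g.nodes):
                data = self._g.nodes[(ns, acc)]
                aliases = "|".join(sorted(data["deprecated_aliases"]))
                attrs = "|".join(
                    f"{k}={v}" for k, v in sorted(data["attributes"].items())
                )
                fh.write(f"{ns}\t{acc}\t{aliases}\t{attrs}\n")
        with open(edge_path, "w") as fh:
            fh.write(
                "namespace_a\taccession_a\tnamespace_b\taccession_b\t"
                "link_kind\tprovenance\tinferred\n"
            )
            rows = sorted(
                (min(a, b), max(a, b), d["link_kind"], d["provenance"], d["inferred"])
                for a, b, d in self._g.edges(data=True)
            )
            for a, b, kind, prov, inferred in rows:
                fh.write(
                    f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{kind}\t{prov}\t"
                    f"{int(inferred)}\n"
                )


# -- construction ----------------------------------------------------------


def build_ontology(
    reference_proteome: Iterable[str],
    crossref_tables: Iterable[CrossrefTable],
) -> OntologyGraph:
    """Assemble the ontology graph over a reference proteome.

    Protein nodes are exactly the supplied accessions.  Gene and mRNA nodes
    are admitted only when reachable from a reference protein through the
    supplied cross-reference rows; rows falling outside that closure are
    dropped with a logged count.
    """
    proteome = [strip_version(acc) for acc in reference_proteome]
    if not proteome:
        raise InputError("reference proteome is empty")
    seen: set[str] = set()
    for acc in proteome:
        if acc in seen:
            raise InputError(f"duplicate protein accession: {acc!r}")
        seen.add(acc)

    tables = list(crossref_tables)
    graph = OntologyGraph()
    protein_keys = {("uniprot", acc) for acc in proteome}
    for _, acc in sorted(protein_keys):
        graph.add_node("uniprot", acc)

    # candidate edge list keyed by version-stripped node keys
    candidates: list[tuple[NodeKey, NodeKey, str, str]] = []
    dropped = 0
    for table in tables:
        ns_from, ns_to = table.namespaces
        for acc_from, acc_to in table.rows:
            key_from = (ns_from, strip_version(acc_from))
            key_to = (ns_to, strip_version(acc_to))
            # a uniprot endpoint outside the reference proteome voids the row
            if (key_from[0] == "uniprot" and key_from not in protein_keys) or (
                key_to[0] == "uniprot" and key_to not in protein_keys
            ):
                dropped += 1
                continue
            candidates.append((key_from, key_to, table.link_kind, table.provenance))

    adjacency: dict[NodeKey, set[NodeKey]] = defaultdict(set)
    for key_from, key_to, _, _ in candidates:
        adjacency[key_from].add(key_to)
        adjacency[key_to].add(key_from)

    closure = set(protein_keys)
    frontier = list(protein_keys)
    while frontier:
        nxt: list[NodeKey] = []
        for key in frontier:
            for nb in adjacency.get(key, ()):
                if nb not in closure:
                    closure.add(nb)
                    nxt.append(nb)
        frontier = nxt

    for key_from, key_to, kind, provenance in candidates:
        if key_from in closure and key_to in closure:
            graph.add_node(*key_from)
            graph.add_node(*key_to)
            graph.add_edge(key_from, key_to, kind, provenance=provenance)
        else:
            dropped += 1

    graph.report.dropped_rows = dropped
    if dropped:
        graph.report.log(f"dropped {dropped} cross-reference rows outside closure")
    graph.check_closure()
    return graph


def infer_indirect_links(
    graph: OntologyGraph,
    gene_bridge: Iterable[tuple[str, str]] = (),
    mrna_bridge: Iterable[tuple[str, str]] = (),
) -> OntologyGraph:
    """Add bridge edges making indirect Entrez links traversable.

    ``gene_bridge`` rows map Ensembl gene -> Entrez gene; ``mrna_bridge``
    rows map EMBL mRNA -> Ensembl gene.  A bridge row whose source node is
    absent from the graph is skipped and logged.  The bridge target node is
    created when missing (it enters the closure through the bridge).  The
    mRNA bridge is applied first so that chained EMBL->Ensembl->Entrez
    paths become traversable in one pass.  No existing edge is removed.
    """
    inferred = 0
    for embl_acc, ensembl_acc in mrna_bridge:
        src = ("mrna_embl", strip_version(embl_acc))
        if src not in graph:
            graph.report.log(f"mrna_bridge row skipped, absent source: {embl_acc}")
            continue
        dst = graph.add_node("gene_ensembl", ensembl_acc)
        if graph.add_edge(src, dst, "gene_ensembl-mrna_embl", provenance="mrna_bridge", inferred=True):
            inferred += 1
    for ensembl_acc, entrez_acc in gene_bridge:
        src = ("gene_ensembl", strip_version(ensembl_acc))
        if src not in graph:
            graph.report.log(f"gene_bridge row skipped, absent source: {ensembl_acc}")
            continue
        dst = graph.add_node("gene_genbank", entrez_acc)
        if graph.add_edge(src, dst, "gene_ensembl-gene_genbank", provenance="gene_bridge", inferred=True):
            inferred += 1
    graph.report.inferred_edges += inferred
    graph.check_closure()
    return graph


def apply_identifier_updates(
    graph: OntologyGraph,
    updates: Mapping[str, str],
    obsolete: Iterable[str] = (),
) -> OntologyGraph:
    """Record deprecated accessions as aliases and drop obsolete entries.

    For an update old->new the active node carrying ``new`` gains ``old``
    as a deprecated alias; if a node keyed by ``old`` still exists in the
    same namespace its edges are folded into the active node first.
    Obsolete accessions are removed together with their edges.  Changes are
    appended to the graph's build report.
    """
    obsolete_set = {strip_version(acc) for acc in obsolete}
    overlap = obsolete_set & {strip_version(k) for k in updates}
    if overlap:
        raise InputError(f"accessions both updated and obsolete: {sorted(overlap)}")

    for old, new in sorted(updates.items()):
        old_stem, new_stem = strip_version(old), strip_version(new)
        targets = [
            key for key in graph.node_keys() if key[1] == new_stem
        ]
        if not targets:
            graph.report.log(f"update target absent, skipped: {old} -> {new}")
            continue
        if len(targets) > 1:
            graph.report.log(f"update target ambiguous, skipped: {old} -> {new}")
            continue
        target = targets[0]
        old_key = (target[0], old_stem)
        if old_key in graph:
            g = graph.nx_graph
            for _, nb, data in list(g.edges(nbunch=[old_key], data=True)):
                if nb != target:
                    graph.add_edge(target, nb, data["link_kind"],
                                   provenance=data["provenance"],
                                   inferred=data["inferred"])
            g.remove_node(old_key)
        graph.add_alias(target, old_stem)
        graph.report.updates_applied += 1
        graph.report.log(f"deprecated {old} now aliases {target[0]}:{target[1]}")

    g = graph.nx_graph
    for acc in sorted(obsolete_set):
        victims = [key for key in list(g.nodes) if key[1] == acc]
        for key in victims:
            n_edges = g.degree(key)
            g.remove_node(key)
            graph.report.obsolete_removed += 1
            graph.report.log(f"obsolete {key[0]}:{key[1]} removed with {n_edges} edges")
    # way-point nodes left isolated by removals are dropped silently
    isolated = [k for k in list(g.nodes) if g.degree(k) == 0 and k[0] != "uniprot"]
    g.remove_nodes_from(isolated)
    return graph


def resolve_identifier(
    graph: OntologyGraph, token: str, namespace_hint: str | None = None
) -> set[OntologyNode]:
    """Resolve a free-form token to the matching active ontology nodes."""
    return {graph.node(key) for key in graph.resolve(token, namespace_hint)}


# -- file-based inputs -----------------------------------------------------


def read_proteome(path: str | Path) -> list[str]:
    """Read a one-accession-per-line reference proteome list."""
    accs = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not accs:
        raise InputError(f"no accessions in proteome file {path}")
    return accs


def read_crossref_table(path: str | Path) -> list[CrossrefTable]:
    """Read a 4-column TSV (namespace_from, accession_from, namespace_to,
    accession_to) into per-link-kind tables."""
    grouped: dict[str, list[tuple[str, str]]] = defaultdict(list)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["namespace_from", "accession_from", "namespace_to", "accession_to"]
        if header != expected:
            raise InputError(f"bad crossref header in {path}: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns")
            ns_from, acc_from, ns_to, acc_to = parts
            kind = link_kind_for(ns_from, ns_to)
            if kind is None:
                raise ConfigurationError(
                    f"{path}:{lineno}: no link kind joins {ns_from} and {ns_to}"
                )
            a, b = LINK_KINDS[kind]
            row = (acc_from, acc_to) if ns_from == a else (acc_to, acc_from)
            grouped[kind].append(row)
    name = Path(path).name
    return [
        CrossrefTable(link_kind=kind, rows=rows, provenance=name)
        for kind, rows in sorted(grouped.items())
    ]


def read_bridge_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV bridge table (source accession, target accession)."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            rows.append((parts[0], parts[1]))
    return rows
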