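"""Reversibly project the hybrid network to the protein or gene level.

Normalization traverses the ontology graph from each interactor towards
the target level and replaces the association by the Cartesian product of
the endpoint correspondent sets.  Every normalized interaction keeps
back-links to the primary associations that produced it, so the
transformation is reversible and no source information is lost.

Traversal rule: breadth-first over the typed ontology links, never
expanding beyond a node at the target level and never passing *through* a
protein node (genetic information flows gene -> mRNA -> protein; proteins
are sinks, and passing through one would leak between unrelated genes via
shared interactors).  The gene level collects GenBank (Entrez) gene nodes
only — Ensembl genes and both mRNA sub-classes are way-points.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .entities import LEVEL_NAMESPACES, LEVELS
from .grading import EvidenceSet
from .hybrid import HybridNetwork, PrimaryAssociation
from .ontology import NodeKey, OntologyGraph

Pair = tuple[NodeKey, NodeKey]


class IntegrityError(RuntimeError):
    """A normalized interaction references a missing primary association."""


def normalize_node(node: NodeKey, level: str, graph: OntologyGraph) -> set[NodeKey]:
    """All correspondents of one ontology node at the target level.

    A node already at the target level is its own singleton correspondent.
    The empty set means the node has no correspondent at that level (e.g.
    a protein never linked, directly or via bridges, to an Entrez gene).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    target_ns = LEVEL_NAMESPACES[level]
    if node[0] in target_ns:
        return {node}
    if node not in graph:
        return set()

    found: set[NodeKey] = set()
    visited = {node}
    frontier = [node]
    while frontier:
        nxt: list[NodeKey] = []
        for current in frontier:
            for neighbor in graph.neighbors(current):
                if neighbor in visited:
                    continue
                visited.add(neighbor)
                if neighbor[0] in target_ns:
                    found.add(neighbor)
                    continue  # target-level nodes terminate traversal
                if neighbor[0] == "uniprot":
                    continue  # never pass through a protein
                nxt.append(neighbor)
        frontier = nxt
    return found


@dataclass
class NormalizedInteraction:
    """A node pair at one level, with back-links to its primary evidence."""

    level: str
    node_a: NodeKey
    node_b: NodeKey
    primary_links: set[str] = field(default_factory=set)
    fanout_flag: bool = False
    artifact_flag: bool = False
    standard_score: int | None = None
    crosschecked_score: int | None = None

    @property
    def pair(self) -> Pair:
        return (self.node_a, self.node_b)

    @property
    def is_self(self) -> bool:
        return self.node_a == self.node_b

    def evidence_view(self, hybrid: HybridNetwork) -> list[EvidenceSet]:
        """All evidence sets inherited through the primary back-links."""
        out: list[EvidenceSet] = []
        for assoc in denormalize(self, hybrid):
            out.extend(assoc.evidence_sets)
        return out


@dataclass
class NormalizedNetwork:
    """The hybrid network projected to one genetic-reference level."""

    level: str
    interactions: dict[Pair, NormalizedInteraction] = field(default_factory=dict)
    #: primary associations with an interactor lacking a correspondent
    orphans: list[str] = field(default_factory=list)
    #: normalized pairs produced by each primary association
    assoc_pairs: dict[str, frozenset[Pair]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[NormalizedInteraction]:
        for pair in sorted(self.interactions):
            yield self.interactions[pair]

    def __len__(self) -> int:
        return len(self.interactions)

    def nodes(self) -> set[NodeKey]:
        out: set[NodeKey] = set()
        for pair in self.interactions:
            out.update(pair)
        return out


def _canonical(a: NodeKey, b: NodeKey) -> Pair:
    return (a, b) if a <= b else (b, a)


def normalize_network(
    hybrid: HybridNetwork, level: str, graph: OntologyGraph
) -> NormalizedNetwork:
    """Project every main-store association to ``level``.

    Each association contributes the Cartesian product of its endpoints'
    correspondent sets; pairs merge across associations.  Self-pairs (both
    endpoints normalizing to one node) are kept and visible via
    ``is_self`` — dropping them would break reversibility.  Associations
    with an endpoint lacking any correspondent go to the orphan log.
    """
    network = NormalizedNetwork(level=level)
    for key in sorted(hybrid.associations):
        assoc = hybrid.associations[key]
        set_a = normalize_node(assoc.node_a, level, graph)
        set_b = normalize_node(assoc.node_b, level, graph)
        if not set_a or not set_b:
            network.orphans.append(assoc.id)
            continue
        fanout = len(set_a) > 1 or len(set_b) > 1
        pairs = {_canonical(x, y) for x in set_a for y in set_b}
        network.assoc_pairs[assoc.id] = frozenset(pairs)
        for pair in sorted(pairs):
            inter = network.interactions.get(pair)
            if inter is None:
                inter = NormalizedInteraction(level=level, node_a=pair[0], node_b=pair[1])
                network.interactions[pair] = inter
            inter.primary_links.add(assoc.id)
            inter.fanout_flag = inter.fanout_flag or fanout
    return network


def denormalize(
    interaction: NormalizedInteraction, hybrid: HybridNetwork
) -> list[PrimaryAssociation]:
    """The primary associations behind one normalized interaction, in their
    original representation."""
    out = []
    for assoc_id in sorted(interaction.primary_links):
        try:
            out.append(hybrid.by_id(assoc_id))
        except KeyError as exc:
            raise IntegrityError(
                f"normalized interaction {interaction.pair} links missing "
                f"primary association {assoc_id}"
            ) from exc
    return out


def side_store_pairs(
    hybrid: HybridNetwork, level: str, graph: OntologyGraph
) -> dict[str, frozenset[Pair]]:
    """Normalized pairs of the protein–gene/RNA side-store associations.

    These never enter the interaction network but their correspondents are
    needed when cross-checking class-5 evidence against it.
    """
    out: dict[str, frozenset[Pair]] = {}
    for key in sorted(hybrid.side_store):
        assoc = hybrid.side_store[key]
        set_a = normalize_node(assoc.node_a, level, graph)
        set_b = normalize_node(assoc.node_b, level, graph)
        if set_a and set_b:
            out[assoc.id] = frozenset(
                _canonical(x, y) for x in set_a for y in set_b
            )
    return out


def export_network(
    network: NormalizedNetwork, hybrid: HybridNetwork, path: str | Path
) -> None:
    """Write the tab-delimited network exchange format.

    One row per interaction: interactors, both confidence scores, distinct
    publication count and keys, contributing sources, and the fan-out /
    normalization-artifact flags.
    """
    with open(path, "w") as fh:
        fh.write(
            "interactor_a\tinteractor_b\tstandard_score\tcrosschecked_score\t"
            "n_publications\tpublications\tsources\tfanout\tartifact\n"
        )
        for inter in network:
            evidences = inter.evidence_view(hybrid)
            pubs = sorted({p for ev in evidences for p in ev.publication_keys})
            sources = sorted({ev.source_db for ev in evidences})
            fh.write(
                f"{inter.node_a[1]}\t{inter.node_b[1]}\t"
                f"{inter.standard_score or ''}\t{inter.crosschecked_score or ''}\t"
                f"{len(pubs)}\t{'|'.join(pubs)}\t{'|'.join(sources)}\t"
                f"{int(inter.fanout_flag)}\t{int(inter.artifact_flag)}\n"
            )
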