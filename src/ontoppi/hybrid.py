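"""Superimpose graded primary records onto the ontology graph.

The result is the heterogeneous "hybrid" network: associations between
ontology nodes of possibly different entity levels (a BioGRID record links
two gene nodes, an IntAct record two protein nodes, an HPRD record two
mRNA nodes), each carrying its graded evidence in original form.  Records
whose interactors cannot be resolved to exactly one active ontology node
are rejected with a reason; protein–gene/RNA associations are stored in a
side store used only for cross-checking; genetic-interference records are
discarded outright.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .grading import EvidenceSet, GradingRuleset, grade_evidence
from .ingest import AssociationKind, RawInteractionRecord, classify_association
from .ontology import NodeKey, OntologyGraph

PairKey = tuple[str, tuple[NodeKey, NodeKey]]  # (source_db, sorted node pair)


@dataclass
class PrimaryAssociation:
    """All evidence one source reports for one pair of ontology nodes."""

    id: str
    source_db: str
    node_a: NodeKey
    node_b: NodeKey
    evidence_sets: list[EvidenceSet] = field(default_factory=list)
    kind: AssociationKind = AssociationKind.PPI_CANDIDATE

    @property
    def pair(self) -> tuple[NodeKey, NodeKey]:
        return tuple(sorted((self.node_a, self.node_b)))  # type: ignore[return-value]

    def add_evidence(self, evidence: EvidenceSet) -> bool:
        """Append unless an exact duplicate evidence is already present."""
        ident = evidence.identity()
        if any(e.identity() == ident for e in self.evidence_sets):
            return False
        self.evidence_sets.append(evidence)
        return True


@dataclass
class Rejection:
    reason: str
    source_db: str
    interactor_a: str
    interactor_b: str


@dataclass
class HybridNetwork:
    """The integrated heterogeneous network plus its side store and log."""

    associations: dict[PairKey, PrimaryAssociation] = field(default_factory=dict)
    side_store: dict[PairKey, PrimaryAssociation] = field(default_factory=dict)
    rejections: list[Rejection] = field(default_factory=list)
    discarded_interference: int = 0

    def all_associations(self) -> Iterator[PrimaryAssociation]:
        yield from self.associations.values()
        yield from self.side_store.values()

    def by_id(self, assoc_id: str) -> PrimaryAssociation:
        for assoc in self.all_associations():
            if assoc.id == assoc_id:
                return assoc
        raise KeyError(assoc_id)

    def evidence_count(self) -> int:
        return sum(len(a.evidence_sets) for a in self.all_associations())


def superimpose(
    records: Iterable[RawInteractionRecord],
    graph: OntologyGraph,
    ruleset: GradingRuleset,
) -> HybridNetwork:
    """Integrate classified, human-filtered records into a hybrid network.

    Each record's interactors are resolved against the ontology by
    namespace and accession (deprecated aliases included).  A record with
    an unresolvable or ambiguous interactor is rejected with a distinct
    reason code — ambiguity is a normalization-time concept and primary
    storage stays faithful to the source.  Records merge per (source,
    unordered pair); exact-duplicate evidence lines collapse to one.
    """
    network = HybridNetwork()
    counters: dict[str, int] = defaultdict(int)
    cv_config = ruleset.cv_config()

    for record in records:
        kind = classify_association(record, cv_config)
        if kind == AssociationKind.GENETIC_INTERFERENCE:
            network.discarded_interference += 1
            continue

        resolved: list[NodeKey] = []
        failure = None
        for ref in (record.interactor_a, record.interactor_b):
            hits = graph.resolve_accession(ref.namespace, ref.accession)
            if not hits:
                failure = "unresolvable_interactor"
                break
            if len(hits) > 1:
                failure = "ambiguous_interactor"
                break
            resolved.append(next(iter(hits)))
        if failure:
            network.rejections.append(
                Rejection(
                    reason=failure,
                    source_db=record.source_db,
                    interactor_a=record.interactor_a.accession,
                    interactor_b=record.interactor_b.accession,
                )
            )
            continue

        node_a, node_b = resolved
        evidence = EvidenceSet(
            source_db=record.source_db,
            interaction_type_term=record.interaction_type,
            detection_method_term=record.detection_method,
            throughput_or_expansion=record.throughput_or_expansion,
            publication_keys=frozenset(record.publications),
        )
        evidence.standard_class = grade_evidence(evidence, ruleset, kind)
        evidence.validate()

        store = (
            network.side_store
            if kind == AssociationKind.PROTEIN_GENE_OR_RNA
            else network.associations
        )
        key: PairKey = (record.source_db, tuple(sorted((node_a, node_b))))  # type: ignore[assignment]
        if key not in store:
            counters[record.source_db] += 1
            store[key] = PrimaryAssociation(
                id=f"{record.source_db}:{counters[record.source_db]}",
                source_db=record.source_db,
                node_a=key[1][0],
                node_b=key[1][1],
                kind=kind,
            )
        assoc = store[key]
        assoc.add_evidence(evidence)
        evidence.origin_record_id = assoc.id
    return network


def unfiltered_membership(network: HybridNetwork) -> set[PairKey]:
    """Associations supported by at least one class <=3 evidence.

    Associations backed only by class-5 evidence stay out of every
    interaction network; they exist purely for cross-checking.
    """
    members: set[PairKey] = set()
    for key, assoc in network.associations.items():
        for evidence in assoc.evidence_sets:
            if evidence.standard_class is None:
                raise RuntimeError(f"ungraded evidence on association {assoc.id}")
            if evidence.standard_class <= 3:
                members.add(key)
                break
    return members


def dump_hybrid(network: HybridNetwork, path: str | Path) -> None:
    """Write one row per association-evidence, loss-lessly re-loadable."""
    with open(path, "w") as fh:
        fh.write(
            "association_id\tstore\tsource_db\tnamespace_a\taccession_a\t"
            "namespace_b\taccession_b\tkind\tinteraction_type\tdetection_method\t"
            "throughput_or_expansion\tpublications\tstandard_class\tcrosschecked_class\n"
        )
        for store_name, store in (("main", network.associations), ("side", network.side_store)):
            for key in sorted(store):
                assoc = store[key]
                for ev in assoc.evidence_sets:
                    pubs = "|".join(sorted(ev.publication_keys))
                    fh.write(
                        f"{assoc.id}\t{store_name}\t{assoc.source_db}\t"
                        f"{assoc.node_a[0]}\t{assoc.node_a[1]}\t"
                        f"{assoc.node_b[0]}\t{assoc.node_b[1]}\t{assoc.kind.value}\t"
                        f"{ev.interaction_type_term}\t{ev.detection_method_term}\t"
                        f"{ev.throughput_or_expansion}\t{pubs}\t"
                        f"{ev.standard_class or ''}\t{ev.crosschecked_class or ''}\n"
                    )


def load_hybrid(path: str | Path) -> HybridNetwork:
    """Re-load a hybrid-network dump written by :func:`dump_hybrid`."""
    network = HybridNetwork()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("association_id\t"):
            raise ValueError(f"not a hybrid dump: {path}")
        for line in fh:
            if not line.strip():
                continue
            (
                assoc_id, store_name, source_db, ns_a, acc_a, ns_b, acc_b, kind,
                itype, method, label, pubs, std, xc,
            ) = line.rstrip("\n").split("\t")
            node_a, node_b = (ns_a, acc_a), (ns_b, acc_b)
            store = network.associations if store_name == "main" else network.side_store
            key: PairKey = (source_db, tuple(sorted((node_a, node_b))))  # type: ignore[assignment]
            if key not in store:
                store[key] = PrimaryAssociation(
                    id=assoc_id,
                    source_db=source_db,
                    node_a=key[1][0],
                    node_b=key[1][1],
                    kind=AssociationKind(kind),
                )
            ev = EvidenceSet(
                source_db=source_db,
                interaction_type_term=itype,
                detection_method_term=method,
                throughput_or_expansion=label,
                publication_keys=frozenset(p for p in pubs.split("|") if p),
                standard_class=int(std) if std else None,
                crosschecked_class=int(xc) if xc else None,
                origin_record_id=assoc_id,
            )
            store[key].add_evidence(ev)
    return network
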