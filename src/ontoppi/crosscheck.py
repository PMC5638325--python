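"""Cross-source evidence reconciliation on shared publications.

Source databases curate the same publications under different rules, so
one paper can yield a class-2 evidence in one source and a class-3 (or
class-5 protein–gene/RNA) evidence in another.  Such evidences are not
independent: when they concern the same — or an interrelated, fan-out
linked — normalized interaction, the optimistic class-2 evaluation is
downgraded to a cross-checked class 3.  Class-1 evidences always retain
their classification; the procedure only ever demotes, never promotes.

The same per-publication bookkeeping designates normalization artifacts:
interactions created purely by the fan-out of a coarse (e.g. gene-level)
record, which a finer-grained record from another source for the same
publication contradicts by supporting only a strict subset of them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .grading import EvidenceSet
from .hybrid import HybridNetwork
from .normalize import NormalizedNetwork, Pair, side_store_pairs
from .ontology import OntologyGraph


@dataclass(frozen=True)
class _Entry:
    """One (publication, evidence) occurrence with its normalized footprint."""

    publication: str
    source_db: str
    assoc_id: str
    standard_class: int
    pairs: frozenset[Pair]


@dataclass
class CrosscheckReport:
    """Downgrades applied, one row per affected evidence-publication pair."""

    rows: list[tuple[str, str, str, int, int, str]] = field(default_factory=list)
    # (publication, assoc_id, source, standard, crosschecked, trigger source)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "publication\tassociation\tsource\tstandard_class\t"
                "crosschecked_class\ttrigger_source\n"
            )
            for row in sorted(self.rows):
                fh.write("\t".join(str(x) for x in row) + "\n")


def _evidence_entries(
    hybrid: HybridNetwork,
    assoc_pairs: dict[str, frozenset[Pair]],
) -> list[tuple[EvidenceSet, list[_Entry]]]:
    out = []
    for assoc in hybrid.all_associations():
        pairs = assoc_pairs.get(assoc.id)
        if pairs is None:
            continue  # orphaned at this level; locality keeps it untouched
        for ev in assoc.evidence_sets:
            if ev.standard_class is None:
                raise RuntimeError(f"ungraded evidence on association {assoc.id}")
            entries = [
                _Entry(
                    publication=pub,
                    source_db=assoc.source_db,
                    assoc_id=assoc.id,
                    standard_class=ev.standard_class,
                    pairs=pairs,
                )
                for pub in sorted(ev.publication_keys)
            ]
            out.append((ev, entries))
    return out


def compute_crosschecked_classes(
    network: NormalizedNetwork,
    hybrid: HybridNetwork,
    graph: OntologyGraph,
) -> CrosscheckReport:
    """Assign every evidence its cross-checked class at ``network.level``.

    A standard class-2 evidence is downgraded to cross-checked class 3
    exactly when another source contributes, for the same publication, a
    class-3 or class-5 evidence whose normalized footprint shares at least
    one interaction with it.  Every other evidence keeps its standard
    class.  Idempotent: the result depends only on standard classes.
    """
    footprints = dict(network.assoc_pairs)
    footprints.update(side_store_pairs(hybrid, network.level, graph))
    tagged = _evidence_entries(hybrid, footprints)

    by_pub: dict[str, list[_Entry]] = defaultdict(list)
    for _, entries in tagged:
        for e in entries:
            by_pub[e.publication].append(e)

    report = CrosscheckReport()
    for ev, entries in tagged:
        ev.crosschecked_class = ev.standard_class
        if ev.standard_class != 2:
            continue
        for e in entries:
            trigger = next(
                (
                    f
                    for f in by_pub[e.publication]
                    if f.source_db != e.source_db
                    and f.standard_class in (3, 5)
                    and (f.pairs & e.pairs)
                ),
                None,
            )
            if trigger is not None:
                ev.crosschecked_class = 3
                report.rows.append(
                    (
                        e.publication,
                        e.assoc_id,
                        e.source_db,
                        ev.standard_class,
                        ev.crosschecked_class,
                        trigger.source_db,
                    )
                )
                break
    return report


def flag_normalization_artifacts(
    network: NormalizedNetwork,
    hybrid: HybridNetwork,
    graph: OntologyGraph,
) -> set[Pair]:
    """Flag interactions that exist purely through contradicted fan-out.

    For one publication, when source A's evidence fans out to a set S of
    normalized interactions and source B supports only a strict, non-empty
    subset of S, the interactions in the complement whose entire evidence
    derives from fan-out are flagged as potential normalization artifacts.
    The flag is an annotation only — network membership is still decided
    by the confidence scores.  The subset rule is a deliberately minimal
    heuristic and is labelled as such in exports.
    """
    footprints = dict(network.assoc_pairs)
    side = side_store_pairs(hybrid, network.level, graph)
    footprints.update(side)
    tagged = _evidence_entries(hybrid, footprints)

    by_pub: dict[str, list[_Entry]] = defaultdict(list)
    for _, entries in tagged:
        for e in entries:
            by_pub[e.publication].append(e)

    def _pure_fanout(pair: Pair) -> bool:
        inter = network.interactions.get(pair)
        if inter is None:
            return False
        return all(
            len(network.assoc_pairs.get(assoc_id, frozenset())) > 1
            for assoc_id in inter.primary_links
        )

    flagged: set[Pair] = set()
    for pub, entries in by_pub.items():
        for e in entries:
            if len(e.pairs) <= 1:
                continue  # no fan-out, nothing to contradict
            support_by_source: dict[str, set[Pair]] = defaultdict(set)
            for f in entries:
                if f.source_db != e.source_db:
                    support_by_source[f.source_db].update(f.pairs & e.pairs)
            for overlap in support_by_source.values():
                if overlap and overlap < e.pairs:
                    for pair in e.pairs - overlap:
                        if _pure_fanout(pair):
                            flagged.add(pair)
    for pair in flagged:
        network.interactions[pair].artifact_flag = True
    return flagged
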