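"""Score normalized interactions, apply filtering modes, serve queries.

An interaction's confidence score is the best (minimum) class over its
inherited evidence, computed once from the standard classes and once from
the cross-checked classes.  Three nested filtering modes follow:

- unfiltered            — standard score <= 3 (everything except the
                          protein–gene/RNA class-5 material),
- standard              — standard score <= 2,
- cross-checked default — cross-checked score <= 2 (the most refined view).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import networkx as nx

from .hybrid import HybridNetwork
from .normalize import (
    IntegrityError,
    NormalizedInteraction,
    NormalizedNetwork,
    Pair,
)
from .ontology import NodeKey


class FilterMode(str, Enum):
    UNFILTERED = "unfiltered"
    STANDARD = "standard"
    CROSSCHECKED_DEFAULT = "default"


class QueryScope(str, Enum):
    FIRST_NEIGHBORS = "first_neighbors"
    NEIGHBORS_PLUS_INTERCONNECTIONS = "neighbors_plus_interconnections"
    AMONG_QUERIED = "among_queried"


def score_interaction(
    interaction: NormalizedInteraction, hybrid: HybridNetwork
) -> tuple[int, int]:
    """(standard, cross-checked) confidence scores of one interaction."""
    evidences = interaction.evidence_view(hybrid)
    if not evidences:
        raise IntegrityError(f"interaction {interaction.pair} has no evidence")
    standard = min(ev.standard_class for ev in evidences)
    crosschecked = min(
        ev.crosschecked_class
        if ev.crosschecked_class is not None
        else ev.standard_class
        for ev in evidences
    )
    return standard, crosschecked


def score_network(network: NormalizedNetwork, hybrid: HybridNetwork) -> None:
    for interaction in network:
        interaction.standard_score, interaction.crosschecked_score = score_interaction(
            interaction, hybrid
        )


def apply_filter(network: NormalizedNetwork, mode: FilterMode) -> NormalizedNetwork:
    """Materialize one filtering mode as a new network view.

    Class-5-only interactions (score 5) are outside even the unfiltered
    network; they live in the side store only.
    """
    def keep(inter: NormalizedInteraction) -> bool:
        if inter.standard_score is None or inter.crosschecked_score is None:
            raise RuntimeError(f"unscored interaction {inter.pair}")
        if mode == FilterMode.UNFILTERED:
            return inter.standard_score <= 3
        if mode == FilterMode.STANDARD:
            return inter.standard_score <= 2
        return inter.crosschecked_score <= 2

    kept = {pair: inter for pair, inter in network.interactions.items() if keep(inter)}
    return NormalizedNetwork(
        level=network.level,
        interactions=kept,
        orphans=list(network.orphans),
        assoc_pairs=dict(network.assoc_pairs),
    )


@dataclass
class QueryRequest:
    entities: set[NodeKey]
    level: str
    mode: FilterMode = FilterMode.CROSSCHECKED_DEFAULT
    scope: QueryScope = QueryScope.FIRST_NEIGHBORS

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("query requires at least one entity")


@dataclass
class QueryResult:
    """One result row; the first interactor is always a queried entity."""

    first: NodeKey
    second: NodeKey
    interaction: NormalizedInteraction
    n_publications: int = 0


def query(
    network: NormalizedNetwork, request: QueryRequest, hybrid: HybridNetwork
) -> list[QueryResult]:
    """Retrieve interactions per the requested scope, deterministically ordered.

    Ordering: cross-checked score ascending, then standard score ascending,
    then distinct supporting-publication count descending, ties broken
    lexicographically by partner accession.  Entities absent from the
    network contribute nothing.
    """
    if network.level != request.level:
        raise ValueError(
            f"network level {network.level!r} does not match request {request.level!r}"
        )
    queried = set(request.entities)

    def touches(pair: Pair) -> bool:
        return pair[0] in queried or pair[1] in queried

    selected: list[NormalizedInteraction] = []
    if request.scope == QueryScope.AMONG_QUERIED:
        selected = [
            inter
            for pair, inter in network.interactions.items()
            if pair[0] in queried and pair[1] in queried
        ]
    else:
        incident = [
            inter for pair, inter in network.interactions.items() if touches(pair)
        ]
        selected = list(incident)
        if request.scope == QueryScope.NEIGHBORS_PLUS_INTERCONNECTIONS:
            neighbors: set[NodeKey] = set()
            for inter in incident:
                neighbors.update(inter.pair)
            neighbors -= queried
            selected += [
                inter
                for pair, inter in network.interactions.items()
                if pair[0] in neighbors and pair[1] in neighbors and not touches(pair)
            ]

    results = []
    for inter in selected:
        first, second = inter.pair
        if first not in queried and second in queried:
            first, second = second, first
        pubs = {
            p for ev in inter.evidence_view(hybrid) for p in ev.publication_keys
        }
        results.append(
            QueryResult(first=first, second=second, interaction=inter,
                        n_publications=len(pubs))
        )
    results.sort(
        key=lambda r: (
            r.interaction.crosschecked_score
            if r.interaction.crosschecked_score is not None
            else 9,
            r.interaction.standard_score
            if r.interaction.standard_score is not None
            else 9,
            -r.n_publications,
            r.second[1],
            r.first[1],
        )
    )
    return results


def summarize(network: NormalizedNetwork, hybrid: HybridNetwork | None = None) -> dict:
    """Summary counts: nodes, interactions, score histograms, degrees,
    connected components, and per-source unique contributions."""
    g = nx.Graph()
    for pair in network.interactions:
        g.add_edge(*pair)
    standard_counts = Counter(
        inter.standard_score for inter in network if inter.standard_score is not None
    )
    crosschecked_counts = Counter(
        inter.crosschecked_score
        for inter in network
        if inter.crosschecked_score is not None
    )
    unique_by_source: Counter[str] = Counter()
    if hybrid is not None:
        for inter in network:
            sources = {ev.source_db for ev in inter.evidence_view(hybrid)}
            if len(sources) == 1:
                unique_by_source[next(iter(sources))] += 1
    degrees: Counter = Counter()
    for a, b in network.interactions:
        degrees[a] += 1
        if b != a:
            degrees[b] += 1  # self-interactions count once
    degree_distribution = Counter(degrees.values())
    return {
        "n_nodes": g.number_of_nodes(),
        "n_interactions": len(network.interactions),
        "n_self_interactions": sum(1 for i in network if i.is_self),
        "standard_score_counts": dict(standard_counts),
        "crosschecked_score_counts": dict(crosschecked_counts),
        "unique_contributions": dict(unique_by_source),
        "degree_distribution": {int(k): v for k, v in sorted(degree_distribution.items())},
        "n_components": nx.number_connected_components(g) if len(g) else 0,
        "n_orphans": len(network.orphans),
    }
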