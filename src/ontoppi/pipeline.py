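"""End-to-end orchestration: files in, filtered normalized networks out.

Thin glue over the library modules, used by the CLI, the test suite and
any script driving a whole integration run on a file bundle laid out the
way the fixture generator writes one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .crosscheck import (
    CrosscheckReport,
    compute_crosschecked_classes,
    flag_normalization_artifacts,
)
from .grading import GradingRuleset, load_ruleset
from .hybrid import HybridNetwork, superimpose
from .ingest import (
    IngestReport,
    RawInteractionRecord,
    convert_hprd_terms,
    filter_human,
    read_hprd,
    read_psimitab,
)
from .network import FilterMode, apply_filter, score_network
from .normalize import NormalizedNetwork, normalize_network
from .ontology import (
    OntologyGraph,
    build_ontology,
    infer_indirect_links,
    read_bridge_table,
    read_crossref_table,
    read_proteome,
)

MITAB_SOURCES = ("biogrid", "intact", "mint", "dip")


def build_graph_from_files(
    proteome_path: str | Path,
    crossref_path: str | Path,
    gene_bridge_path: str | Path | None = None,
    mrna_bridge_path: str | Path | None = None,
) -> OntologyGraph:
    graph = build_ontology(
        read_proteome(proteome_path), read_crossref_table(crossref_path)
    )
    gene_bridge = (
        read_bridge_table(gene_bridge_path)
        if gene_bridge_path and Path(gene_bridge_path).exists()
        else []
    )
    mrna_bridge = (
        read_bridge_table(mrna_bridge_path)
        if mrna_bridge_path and Path(mrna_bridge_path).exists()
        else []
    )
    if gene_bridge or mrna_bridge:
        infer_indirect_links(graph, gene_bridge=gene_bridge, mrna_bridge=mrna_bridge)
    return graph


def ingest_directory(
    directory: str | Path, ruleset: GradingRuleset
) -> tuple[list[RawInteractionRecord], IngestReport]:
    """Read every recognized source file in a bundle directory."""
    directory = Path(directory)
    report = IngestReport()
    records: list[RawInteractionRecord] = []
    for source in MITAB_SOURCES:
        path = directory / f"{source}.mitab"
        if path.exists() and path.stat().st_size > 0:
            records.extend(read_psimitab(path, source, report))
    binary = directory / "hprd_binary.tsv"
    mapping = directory / "hprd_mapping.tsv"
    if binary.exists() and binary.stat().st_size > 0:
        hprd = read_hprd(binary, mapping, report)
        records.extend(
            convert_hprd_terms(hprd, ruleset.hprd_term_conversion)
        )
    return records, report


@dataclass
class PipelineResult:
    graph: OntologyGraph
    records: list[RawInteractionRecord]
    ingest_report: IngestReport
    hybrid: HybridNetwork
    #: level -> fully scored, cross-checked, artifact-flagged network
    networks: dict[str, NormalizedNetwork] = field(default_factory=dict)
    crosscheck_reports: dict[str, CrosscheckReport] = field(default_factory=dict)

    def filtered(self, level: str, mode: FilterMode) -> NormalizedNetwork:
        return apply_filter(self.networks[level], mode)


def run_pipeline(
    directory: str | Path,
    levels: tuple[str, ...] = ("protein", "gene"),
    ruleset: GradingRuleset | None = None,
) -> PipelineResult:
    """Run the whole integration on one bundle directory.

    Per level: normalize, cross-check evidence on shared publications,
    score, and flag normalization artifacts.  Cross-checked classes are
    recomputed per level (an evidence's cross-checked class is a
    level-specific judgement; scores are captured level by level).
    """
    directory = Path(directory)
    ruleset = ruleset or load_ruleset()
    graph = build_graph_from_files(
        directory / "proteome.txt",
        directory / "crossref.tsv",
        directory / "gene_bridge.tsv",
        directory / "mrna_bridge.tsv",
    )
    records, ingest_report = ingest_directory(directory, ruleset)
    human = filter_human(records)
    hybrid = superimpose(human, graph, ruleset)
    result = PipelineResult(
        graph=graph,
        records=records,
        ingest_report=ingest_report,
        hybrid=hybrid,
    )
    for level in levels:
        network = normalize_network(hybrid, level, graph)
        result.crosscheck_reports[level] = compute_crosschecked_classes(
            network, hybrid, graph
        )
        score_network(network, hybrid)
        flag_normalization_artifacts(network, hybrid, graph)
        result.networks[level] = network
    return result
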