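"""Level normalization: correspondent sets, fan-out, reversibility."""

import itertools
import random

import pytest

from ontoppi.entities import EntityRef
from ontoppi.grading import load_ruleset
from ontoppi.hybrid import superimpose
from ontoppi.ingest import RawInteractionRecord
from ontoppi.normalize import denormalize, normalize_network, normalize_node
from ontoppi.ontology import CrossrefTable, build_ontology
from ontoppi.pipeline import run_pipeline

RULESET = load_ruleset()
GNAS = ("O95467", "P63092", "P84996", "Q5JWF2")


@pytest.fixture(scope="module")
def graph():
    rows = [(p, "2778") for p in GNAS] + [("Q16658", "6624")]
    return build_ontology(
        list(GNAS) + ["Q16658"],
        [CrossrefTable("uniprot-gene_genbank", rows)],
    )


def test_multiprotein_gene_normalizes_to_all_its_proteins(graph):
    out = normalize_node(("gene_genbank", "2778"), "protein", graph)
    assert out == {("uniprot", p) for p in GNAS}


def test_node_at_target_level_is_its_own_singleton(graph):
    assert normalize_node(("uniprot", "Q16658"), "protein", graph) == {
        ("uniprot", "Q16658")
    }


def test_protein_without_gene_has_no_gene_correspondent():
    graph = build_ontology(["P1"], [])
    assert normalize_node(("uniprot", "P1"), "gene", graph) == set()


def _oracle_reachable(graph, start, level):
    """Brute-force: enumerate simple paths that never pass through a
    protein or a target-level node, collect target-level endpoints."""
    target_ns = {"uniprot"} if level == "protein" else {"gene_genbank"}
    if start[0] in target_ns:
        return {start}
    edges = [(a, b) for a, b, _ in graph.edges()]
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    found = set()
    stack = [(start, {start})]
    while stack:
        node, seen = stack.pop()
        for nb in adj.get(node, ()):
            if nb in seen:
                continue
            if nb[0] in target_ns:
                found.add(nb)
                continue
            if nb[0] == "uniprot":
                continue
            stack.append((nb, seen | {nb}))
    return found


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_normalize_node_matches_path_enumeration_oracle(seed):
    rng = random.Random(seed)
    proteome = [f"P{i}" for i in range(8)]
    genes = [str(i) for i in range(100, 105)]
    mrnas = [f"NM_{i}" for i in range(5)]
    tables = [
        CrossrefTable("uniprot-gene_genbank",
                      [(rng.choice(proteome), rng.choice(genes)) for _ in range(10)]),
        CrossrefTable("gene_genbank-mrna_refseq",
                      [(rng.choice(genes), rng.choice(mrnas)) for _ in range(6)]),
        CrossrefTable("uniprot-mrna_refseq",
                      [(rng.choice(proteome), rng.choice(mrnas)) for _ in range(6)]),
    ]
    graph = build_ontology(proteome, tables)
    for node in graph.node_keys():
        for level in ("protein", "gene"):
            assert normalize_node(node, level, graph) == _oracle_reachable(
                graph, node, level
            ), (node, level)


def _worked_records():
    def rec(source, ns, a, b, **attrs):
        attributes = {
            "interaction_type": "physical association",
            "detection_method": "anti bait coimmunoprecipitation",
            "throughput_or_expansion": "",
            "publications": ("17353931",),
        }
        attributes.update(attrs)
        return RawInteractionRecord(
            source_db=source,
            interactor_a=EntityRef(ns, a),
            interactor_b=EntityRef(ns, b),
            taxid_a=9606,
            taxid_b=9606,
            attributes=attributes,
        )

    return [
        rec("biogrid", "gene_genbank", "2778", "6624",
            detection_method="affinity capture-ms",
            throughput_or_expansion="high throughput"),
        rec("intact", "uniprot", "P63092", "Q16658"),
    ]


def test_gene_level_association_explodes_into_four_protein_interactions(graph):
    hybrid = superimpose(_worked_records()[:1], graph, RULESET)
    network = normalize_network(hybrid, "protein", graph)
    assert len(network) == 4
    assert all(inter.fanout_flag for inter in network)
    expected = {
        tuple(sorted((("uniprot", p), ("uniprot", "Q16658")))) for p in GNAS
    }
    assert set(network.interactions) == expected


def test_same_association_is_identity_at_gene_level(graph):
    hybrid = superimpose(_worked_records()[:1], graph, RULESET)
    network = normalize_network(hybrid, "gene", graph)
    assert set(network.interactions) == {
        (("gene_genbank", "2778"), ("gene_genbank", "6624"))
    }
    [inter] = list(network)
    assert not inter.fanout_flag


def test_denormalize_returns_original_primary_associations(graph):
    hybrid = superimpose(_worked_records(), graph, RULESET)
    network = normalize_network(hybrid, "protein", graph)
    pair = tuple(sorted((("uniprot", "P63092"), ("uniprot", "Q16658"))))
    sources = {a.source_db for a in denormalize(network.interactions[pair], hybrid)}
    assert sources == {"biogrid", "intact"}
    single = tuple(sorted((("uniprot", "O95467"), ("uniprot", "Q16658"))))
    [assoc] = denormalize(network.interactions[single], hybrid)
    assert assoc.source_db == "biogrid"
    assert assoc.node_a == ("gene_genbank", "2778")  # original representation


def _random_hybrid(graph, seed, n=40):
    rng = random.Random(seed)
    proteins = list(GNAS) + ["Q16658"]
    entities = [("uniprot", p) for p in proteins] + [
        ("gene_genbank", "2778"), ("gene_genbank", "6624")
    ]
    records = []
    for i in range(n):
        (ns_a, a), (ns_b, b) = rng.sample(entities, 2)
        if ns_a != ns_b and rng.random() < 0.5:
            continue  # bias towards same-level pairs, mixed are fine too
        records.append(
            RawInteractionRecord(
                source_db=rng.choice(["biogrid", "intact"]),
                interactor_a=EntityRef(ns_a, a),
                interactor_b=EntityRef(ns_b, b),
                taxid_a=9606,
                taxid_b=9606,
                attributes={
                    "interaction_type": "physical association",
                    "detection_method": "pull down",
                    "throughput_or_expansion": "",
                    "publications": (str(rng.randint(1, 9)),),
                },
            )
        )
    return superimpose(records, graph, RULESET)


@pytest.mark.parametrize("seed", [3, 4])
def test_network_matches_product_and_merge_oracle(graph, seed):
    hybrid = _random_hybrid(graph, seed)
    network = normalize_network(hybrid, "protein", graph)
    expected = {}
    for assoc in hybrid.associations.values():
        set_a = _oracle_reachable(graph, assoc.node_a, "protein")
        set_b = _oracle_reachable(graph, assoc.node_b, "protein")
        for x, y in itertools.product(set_a, set_b):
            expected.setdefault(tuple(sorted((x, y))), set()).add(assoc.id)
    assert {p: i.primary_links for p, i in network.interactions.items()} == expected


@pytest.mark.parametrize("level", ["protein", "gene"])
def test_round_trip_reproduces_network(graph, level):
    hybrid = _random_hybrid(graph, seed=5)
    network = normalize_network(hybrid, level, graph)
    recovered_ids = set()
    for inter in network:
        for assoc in denormalize(inter, hybrid):
            recovered_ids.add(assoc.id)
    assert recovered_ids == {
        a.id for a in hybrid.associations.values() if a.id not in network.orphans
    }
    renormalized = normalize_network(hybrid, level, graph)
    assert set(renormalized.interactions) == set(network.interactions)
    for pair in network.interactions:
        assert (
            renormalized.interactions[pair].primary_links
            == network.interactions[pair].primary_links
        )


def test_evidence_conservation_across_levels(graph):
    hybrid = _random_hybrid(graph, seed=6)

    def multiset(level):
        network = normalize_network(hybrid, level, graph)
        out = []
        for assoc_id in set().union(
            *(i.primary_links for i in network), set()
        ):
            assoc = hybrid.by_id(assoc_id)
            out.extend((assoc_id, e.identity()) for e in assoc.evidence_sets)
        return sorted(out)

    assert multiset("protein") == multiset("gene")


def test_fanout_bound(graph):
    hybrid = superimpose(_worked_records()[:1], graph, RULESET)
    network = normalize_network(hybrid, "protein", graph)
    [assoc] = hybrid.associations.values()
    set_a = normalize_node(assoc.node_a, "protein", graph)
    set_b = normalize_node(assoc.node_b, "protein", graph)
    n_pairs = len(network.assoc_pairs[assoc.id])
    # unordered-pair count of the Cartesian product: |A||B| minus the
    # duplicates collapsed when both endpoints land in the overlap
    overlap = len(set_a & set_b)
    assert n_pairs == len(set_a) * len(set_b) - overlap * (overlap - 1) // 2
    assert n_pairs == 4


def test_self_pairs_kept_and_flagged():
    rows = [("PA", "99"), ("PB", "99")]
    graph = build_ontology(["PA", "PB"], [CrossrefTable("uniprot-gene_genbank", rows)])
    record = RawInteractionRecord(
        source_db="intact",
        interactor_a=EntityRef("uniprot", "PA"),
        interactor_b=EntityRef("uniprot", "PB"),
        taxid_a=9606,
        taxid_b=9606,
        attributes={
            "interaction_type": "physical association",
            "detection_method": "pull down",
            "throughput_or_expansion": "",
            "publications": ("1",),
        },
    )
    hybrid = superimpose([record], graph, RULESET)
    network = normalize_network(hybrid, "gene", graph)
    [inter] = list(network)
    assert inter.is_self and inter.pair == (("gene_genbank", "99"),) * 2


def test_orphan_log_collects_unprojectable_associations(tmp_path):
    # an HPRD-style mRNA pair whose mRNA has a gene but whose partner lacks one
    rows_g = [("PA", "55")]
    rows_m = [("PA", "NM_1")]
    graph = build_ontology(
        ["PA", "PB"],
        [
            CrossrefTable("uniprot-gene_genbank", rows_g),
            CrossrefTable("uniprot-mrna_refseq", rows_m + [("PB", "NM_2")]),
        ],
    )
    record = RawInteractionRecord(
        source_db="hprd",
        interactor_a=EntityRef("mrna_refseq", "NM_1"),
        interactor_b=EntityRef("mrna_refseq", "NM_2"),
        taxid_a=9606,
        taxid_b=9606,
        attributes={
            "interaction_type": "physical association",
            "detection_method": "pull down",
            "throughput_or_expansion": "",
            "publications": ("1",),
        },
    )
    hybrid = superimpose([record], graph, RULESET)
    protein_net = normalize_network(hybrid, "protein", graph)
    gene_net = normalize_network(hybrid, "gene", graph)
    assert len(protein_net) == 1  # both mRNAs have protein correspondents
    assert gene_net.orphans == [hybrid.by_id("hprd:1").id]


def test_pipeline_round_trip_on_generated_bundle(random_result):
    hybrid = random_result.hybrid
    for level, network in random_result.networks.items():
        for inter in network:
            for assoc in denormalize(inter, hybrid):
                assert inter.pair in random_result.networks[level].assoc_pairs[assoc.id]
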