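"""Cross-source reconciliation: downgrades and normalization-artifact flags."""

import copy
import random
from collections import defaultdict

import pytest

from ontoppi.crosscheck import compute_crosschecked_classes, flag_normalization_artifacts
from ontoppi.entities import EntityRef
from ontoppi.grading import load_ruleset
from ontoppi.hybrid import superimpose
from ontoppi.ingest import RawInteractionRecord
from ontoppi.normalize import normalize_network, side_store_pairs
from ontoppi.ontology import CrossrefTable, build_ontology

RULESET = load_ruleset()
GNAS = ("O95467", "P63092", "P84996", "Q5JWF2")


def make_graph():
    rows = [(p, "2778") for p in GNAS] + [("Q16658", "6624")]
    return build_ontology(
        list(GNAS) + ["Q16658"],
        [CrossrefTable("uniprot-gene_genbank", rows)],
    )


def rec(source, ns, a, b, cls="2", pub="17353931"):
    attrs = {
        "interaction_type": "physical association",
        "detection_method": "anti bait coimmunoprecipitation",
        "throughput_or_expansion": "",
        "publications": (pub,),
    }
    if cls == "1":
        attrs["interaction_type"] = "direct interaction"
    elif cls == "3":
        attrs["detection_method"] = "affinity capture-ms"
        attrs["throughput_or_expansion"] = "high throughput"
    elif cls == "5":
        attrs["detection_method"] = "affinity capture-rna"
    return RawInteractionRecord(
        source_db=source,
        interactor_a=EntityRef(ns, a),
        interactor_b=EntityRef(ns, b),
        taxid_a=9606,
        taxid_b=9606,
        attributes=attrs,
    )


def run_crosscheck(records, level="protein"):
    graph = make_graph()
    hybrid = superimpose(records, graph, RULESET)
    network = normalize_network(hybrid, level, graph)
    report = compute_crosschecked_classes(network, hybrid, graph)
    return graph, hybrid, network, report


def all_evidences(hybrid):
    return [e for a in hybrid.all_associations() for e in a.evidence_sets]


def test_shared_publication_downgrades_class_two_to_three():
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
    ]
    _, hybrid, _, report = run_crosscheck(records)
    intact_ev = hybrid.by_id("intact:1").evidence_sets[0]
    assert (intact_ev.standard_class, intact_ev.crosschecked_class) == (2, 3)
    biogrid_ev = hybrid.by_id("biogrid:1").evidence_sets[0]
    assert biogrid_ev.crosschecked_class == 3  # unchanged: was already 3
    assert report.rows and report.rows[0][5] == "biogrid"


def test_single_source_network_is_never_downgraded():
    records = [
        rec("intact", "uniprot", "P63092", "Q16658", cls="2", pub="1"),
        rec("intact", "uniprot", "O95467", "Q16658", cls="3", pub="1"),
    ]
    _, hybrid, _, report = run_crosscheck(records)
    assert not report.rows
    for ev in all_evidences(hybrid):
        assert ev.crosschecked_class == ev.standard_class


def test_first_class_evidence_retains_classification():
    records = [
        rec("intact", "uniprot", "P63092", "Q16658", cls="1"),
        rec("biogrid", "uniprot", "P63092", "Q16658", cls="5"),
    ]
    _, hybrid, _, _ = run_crosscheck(records)
    ev = hybrid.by_id("intact:1").evidence_sets[0]
    assert (ev.standard_class, ev.crosschecked_class) == (1, 1)


def test_class_five_side_store_evidence_triggers_downgrade():
    records = [
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
        rec("biogrid", "uniprot", "P63092", "Q16658", cls="5"),
    ]
    _, hybrid, _, _ = run_crosscheck(records)
    ev = hybrid.by_id("intact:1").evidence_sets[0]
    assert ev.crosschecked_class == 3


def test_different_publications_do_not_interact():
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3", pub="111"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2", pub="222"),
    ]
    _, hybrid, _, report = run_crosscheck(records)
    assert not report.rows
    assert hybrid.by_id("intact:1").evidence_sets[0].crosschecked_class == 2


def test_disjoint_footprints_do_not_interact():
    # same publication, but the two records share no normalized interaction
    records = [
        rec("biogrid", "uniprot", "O95467", "P84996", cls="3"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
    ]
    _, hybrid, _, report = run_crosscheck(records)
    assert not report.rows


def test_idempotence():
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
    ]
    graph, hybrid, network, _ = run_crosscheck(records)
    snapshot = [
        (e.standard_class, e.crosschecked_class) for e in all_evidences(hybrid)
    ]
    compute_crosschecked_classes(network, hybrid, graph)
    assert snapshot == [
        (e.standard_class, e.crosschecked_class) for e in all_evidences(hybrid)
    ]


def _oracle_downgrades(hybrid, network, graph):
    """Exhaustive per-publication pairwise scan, independent bookkeeping."""
    footprints = dict(network.assoc_pairs)
    footprints.update(side_store_pairs(hybrid, network.level, graph))
    items = []
    for assoc in hybrid.all_associations():
        if assoc.id not in footprints:
            continue
        for ev in assoc.evidence_sets:
            items.append((assoc, ev))
    downgraded = set()
    for assoc_a, ev_a in items:
        if ev_a.standard_class != 2:
            continue
        for assoc_b, ev_b in items:
            if assoc_b.source_db == assoc_a.source_db:
                continue
            if ev_b.standard_class not in (3, 5):
                continue
            if not (ev_a.publication_keys & ev_b.publication_keys):
                continue
            if footprints[assoc_a.id] & footprints[assoc_b.id]:
                downgraded.add(id(ev_a))
    return downgraded


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_two_source_fixture_matches_pairwise_oracle(seed):
    rng = random.Random(seed)
    proteins = list(GNAS) + ["Q16658"]
    records = []
    for i in range(60):
        a, b = rng.sample(proteins, 2)
        source = rng.choice(["intact", "mint", "biogrid"])
        cls = rng.choice(["1", "2", "2", "3", "5"])
        pub = str(rng.randint(1, 6))
        if source == "biogrid" and rng.random() < 0.4:
            records.append(rec("biogrid", "gene_genbank", "2778", "6624", cls=cls, pub=pub))
        else:
            records.append(rec(source, "uniprot", a, b, cls=cls, pub=pub))
    graph, hybrid, network, _ = run_crosscheck(records)
    expected = _oracle_downgrades(hybrid, network, graph)
    for assoc in hybrid.all_associations():
        if assoc.id not in network.assoc_pairs and assoc.id not in side_store_pairs(
            hybrid, "protein", graph
        ):
            continue
        for ev in assoc.evidence_sets:
            if ev.standard_class == 2:
                assert (ev.crosschecked_class == 3) == (id(ev) in expected)
            else:
                assert ev.crosschecked_class == ev.standard_class


def test_downgrade_only_invariant(random_result):
    for assoc in random_result.hybrid.all_associations():
        for ev in assoc.evidence_sets:
            if ev.crosschecked_class is None:
                continue
            assert ev.crosschecked_class >= ev.standard_class
            if ev.standard_class == 2:
                assert ev.crosschecked_class in (2, 3)


def test_publicationless_evidence_never_altered():
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
    ]
    records[1].attributes["publications"] = ()
    _, hybrid, _, report = run_crosscheck(records)
    assert hybrid.by_id("intact:1").evidence_sets[0].crosschecked_class == 2
    assert not report.rows


# -- normalization artifacts ----------------------------------------------


def test_worked_example_flags_three_fanout_artifacts():
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
    ]
    graph, hybrid, network, _ = run_crosscheck(records)
    flagged = flag_normalization_artifacts(network, hybrid, graph)
    expected = {
        tuple(sorted((("uniprot", p), ("uniprot", "Q16658"))))
        for p in GNAS
        if p != "P63092"
    }
    assert flagged == expected
    pair = tuple(sorted((("uniprot", "P63092"), ("uniprot", "Q16658"))))
    assert not network.interactions[pair].artifact_flag


def test_no_fanout_no_flags():
    records = [
        rec("intact", "uniprot", "P63092", "Q16658", cls="2"),
        rec("mint", "uniprot", "P63092", "Q16658", cls="3"),
    ]
    graph, hybrid, network, _ = run_crosscheck(records)
    assert flag_normalization_artifacts(network, hybrid, graph) == set()


def test_nested_subsets_across_three_sources():
    # biogrid fans out to 4 pairs; intact supports 1 of them; mint supports
    # 2 of them with a different publication (must not trigger for its pub
    # alone since its own footprint has no fan-out)
    records = [
        rec("biogrid", "gene_genbank", "2778", "6624", cls="3", pub="100"),
        rec("intact", "uniprot", "P63092", "Q16658", cls="2", pub="100"),
        rec("mint", "uniprot", "O95467", "Q16658", cls="2", pub="100"),
    ]
    graph, hybrid, network, _ = run_crosscheck(records)
    flagged = flag_normalization_artifacts(network, hybrid, graph)
    # hand enumeration: biogrid footprint S = {O,P63,P84,Q5}xQ16658;
    # other-source support covers O95467 and P63092; P84996 and Q5JWF2
    # remain fan-out-only -> flagged
    expected = {
        tuple(sorted((("uniprot", p), ("uniprot", "Q16658"))))
        for p in ("P84996", "Q5JWF2")
    }
    assert flagged == expected


def test_flags_are_annotations_only(random_result):
    # flagged interactions are still members; flags never change scores
    for network in random_result.networks.values():
        for inter in network:
            assert inter.standard_score is not None
            if inter.artifact_flag:
                assert inter.pair in network.interactions
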