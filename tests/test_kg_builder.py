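from __future__ import annotations

import math

import networkx as nx
import pytest

from kgforge.datastore import Datastore
from kgforge.enrichment import enrichment_score
from kgforge.kg_builder import (
    RELATION_VOCABULARY,
    BuildError,
    BuildParams,
    KnowledgeGraph,
    QuerySpec,
    build_knowledge_graph,
    collect_core_proteins,
    compute_layout,
    expand_neighbours,
    resolve_query_term,
)

from conftest import assert_valid_graph as assert_valid, make_tiny_store


# -------------------------------------------------------------- resolution
def test_resolution_order_and_ambiguity(tiny_store):
    assert resolve_query_term("protein", "P0001", tiny_store) == "P0001"
    assert resolve_query_term("protein", "GEN1", tiny_store) == "P0001"
    assert resolve_query_term("protein", "gen1", tiny_store) == "P0001"
    assert resolve_query_term("disease", "disease one", tiny_store) == "D1"
    assert resolve_query_term("drug", "drug one", tiny_store) == "DRG1"
    with pytest.raises(BuildError, match="unresolvable"):
        resolve_query_term("disease", "no such disease", tiny_store)


def test_query_spec_parsing():
    q = QuerySpec.parse(["gene:MAPK1", "disease:EFO:0000305"])
    assert q.terms == (("protein", "MAPK1"), ("disease", "EFO:0000305"))
    with pytest.raises(BuildError):
        QuerySpec.parse(["justaname"])
    with pytest.raises(BuildError):
        QuerySpec(terms=())


# -------------------------------------------------------------------- core
def test_collect_core_from_disease(tiny_store):
    view = tiny_store.filter_proteins_by_taxon({9606})
    core, prov = collect_core_proteins(QuerySpec((("disease", "D1"),)), view)
    assert core == {"P0001", "P0002", "P0003"}  # mouse P0006 filtered out
    assert prov["disease:D1"] == core


def test_combinatory_query_takes_union(tiny_store):
    view = tiny_store.filter_proteins_by_taxon({9606})
    core, _ = collect_core_proteins(
        QuerySpec((("protein", "GEN5"), ("disease", "D1"))), view
    )
    assert core == {"P0005", "P0001", "P0002", "P0003"}


def test_drug_targets_respect_taxon_filter():
    store = make_tiny_store()
    # give the drug a mouse target as well
    drug = store.drugs["DRG1"]
    object.__setattr__(drug, "target_protein_ids",
                       ("P0001", "P0002", "P0006"))
    store.reindex()
    view = store.filter_proteins_by_taxon({9606})
    core, _ = collect_core_proteins(QuerySpec((("drug", "DRG1"),)), view)
    assert core == {"P0001", "P0002"}


# -------------------------------------------------------------- neighbours
def test_expand_neighbours_scores_match_brute_force(tiny_store):
    view = tiny_store.filter_proteins_by_taxon({9606})
    core = {"P0001", "P0002", "P0003"}
    ranked = expand_neighbours(core, view, k=5)
    ids = [r.term_id for r in ranked]
    assert "P0004" in ids  # linked to two core proteins
    N = view.component_totals["ppi"]
    for r in ranked:
        partners = view.ppi_index[r.term_id]
        m = len(partners & core)
        expected = enrichment_score(
            min(m, min(len(core), N)), min(len(core), N),
            min(len(partners), N), N,
        )
        assert r.E == pytest.approx(expected)


def test_low_degree_neighbour_outranks_promiscuous_one():
    proteins = {f"P{i:03d}": None for i in range(60)}
    from kgforge.datastore import ProteinRecord, PPIRecord

    records = {
        pid: ProteinRecord(pid, f"G{pid}", 9606, True) for pid in proteins
    }
    core = [f"P{i:03d}" for i in range(5)]
    ppis = []
    # specific candidate linked to 3 core proteins only
    for c in core[:3]:
        ppis.append(PPIRecord("P050", c, 0.9))
    # hub candidate linked to the same 3 core proteins plus 47 others
    for c in core[:3]:
        ppis.append(PPIRecord("P051", c, 0.9))
    for i in range(5, 52):
        if f"P{i:03d}" not in ("P050", "P051"):
            ppis.append(PPIRecord("P051", f"P{i:03d}", 0.9))
    store = Datastore(proteins=records, ppis=ppis)
    ranked = expand_neighbours(set(core), store, k=2)
    assert ranked[0].term_id == "P050"


# ------------------------------------------------------------------ build
def test_disease_build_contents_and_invariants(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    assert_valid(graph)
    assert graph.nodes["D1"].role == "query"
    protein_ids = set(graph.protein_ids())
    assert {"P0001", "P0002", "P0003"} <= protein_ids
    assert "P0006" not in protein_ids  # mouse
    # pathway W1 and phenotype H1 are the only candidates -> enriched
    assert "W1" in graph.nodes and "H1" in graph.nodes
    # drug DRG1 targets two graph proteins -> enriched, approved edges
    assert "DRG1" in graph.nodes
    approved = {
        (e.source, e.target)
        for e in graph.edges.values() if e.evidence == "approved"
    }
    assert ("DRG1", "P0001") in approved and ("DRG1", "P0002") in approved


def test_merged_compound_becomes_drug_node(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    # CC1 cross-references DRG1 -> no CC1 compound node, edges on DRG1
    assert "CC1" not in graph.nodes
    assert graph.nodes["DRG1"].component == "drug"
    # CC1's bioactivity against P0003 surfaces on the drug node as an
    # added experimental edge (P0003 is not an approved target)
    e = graph.edges.get(("DRG1", "P0003", "targets", "experimental"))
    assert e is not None and e.weight == pytest.approx(7.0)


def test_evidence_priority_collapse(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    # DRG1-P0002: approved (DrugBank) + experimental (CC1 bioactivity 9.0)
    # must collapse onto the approved edge
    kept = [
        e for e in graph.edges.values()
        if e.relation == "targets" and (e.source, e.target) == ("DRG1", "P0002")
    ]
    assert len(kept) == 1 and kept[0].evidence == "approved"


def test_predicted_only_pair_keeps_predicted_label(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    # DRG1 -> P0003 has predicted evidence too, but experimental wins;
    # CC3 -> P0002 is predicted only
    if "CC3" in graph.nodes:
        edges = [
            e for e in graph.edges.values()
            if e.source == "CC3" and e.target == "P0002"
        ]
        assert edges and edges[0].evidence == "predicted"


def test_include_flags_suppress_evidence_classes(tiny_store):
    params = BuildParams(include_experimental=False, include_predictions=False)
    graph = build_knowledge_graph(["disease:D1"], tiny_store, params)
    assert_valid(graph)
    evidences = {e.evidence for e in graph.edges.values() if e.evidence}
    assert evidences <= {"approved"}


def test_cross_component_edges(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    assert ("DRG1", "D1", "indicates", "") in graph.edges
    assert ("D1", "W1", "modulates", "") in graph.edges
    assert ("D1", "H1", "is associated with", "") in graph.edges


def test_k_zero_adds_no_enriched_terms(tiny_store):
    params = BuildParams(k_per_component={c: 0 for c in
                                          ("protein", "pathway", "disease",
                                           "phenotype", "drug", "compound")})
    graph = build_knowledge_graph(["disease:D1"], tiny_store, params)
    assert_valid(graph)
    assert graph.nodes_of("pathway") == []
    assert graph.nodes_of("drug") == []


def test_unresolvable_query_errors(tiny_store):
    with pytest.raises(BuildError, match="unresolvable"):
        build_knowledge_graph(["disease:NOPE"], tiny_store)


def test_build_caps_each_component(small_store):
    datastore, _ = small_store
    graph = build_knowledge_graph(["disease:D0010"], datastore)
    assert_valid(graph)
    for component in ("pathway", "disease", "phenotype", "drug", "compound"):
        assert len(graph.nodes_of(component, roles=("enriched",))) <= 10


def test_build_deterministic_across_runs(small_store):
    datastore, _ = small_store
    a = build_knowledge_graph(["disease:D0004"], datastore).to_json()
    b = build_knowledge_graph(["disease:D0004"], datastore).to_json()
    assert a == b


def test_build_invariant_under_row_permutation(small_store):
    datastore, _ = small_store
    shuffled = Datastore(
        proteins=dict(reversed(list(datastore.proteins.items()))),
        ppis=list(reversed(datastore.ppis)),
        terms=dict(reversed(list(datastore.terms.items()))),
        drugs=dict(reversed(list(datastore.drugs.items()))),
        compounds=dict(reversed(list(datastore.compounds.items()))),
        bioactivities=list(reversed(datastore.bioactivities)),
        predicted_dtis=list(reversed(datastore.predicted_dtis)),
    )
    a = build_knowledge_graph(["disease:D0004"], datastore).to_json()
    b = build_knowledge_graph(["disease:D0004"], shuffled).to_json()
    assert a == b


def test_related_queries_share_content_unrelated_do_not(small_store):
    """Two diseases of one association block overlap strongly; diseases
    of different blocks barely overlap (diversity/stability pattern)."""
    from kgforge.kg_analysis import node_identity

    datastore, ground_truth = small_store
    block_of = {}
    diseases = [t for t in ground_truth["specific_terms"]["disease"]]
    # specific diseases were planted round-robin over blocks in id order
    same_a, same_b = diseases[0], diseases[3]  # both block 0 territory
    other = diseases[1]  # different block
    g_a = build_knowledge_graph([f"disease:{same_a}"], datastore)
    g_b = build_knowledge_graph([f"disease:{same_b}"], datastore)
    g_c = build_knowledge_graph([f"disease:{other}"], datastore)
    related = node_identity(g_a, g_b).identity_pct
    unrelated = node_identity(g_a, g_c).identity_pct
    assert related > unrelated


# ------------------------------------------------------------------ export
def test_json_round_trip_preserves_census(tiny_store, tmp_path):
    from kgforge.kg_analysis import graph_statistics

    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    compute_layout(graph)
    path = tmp_path / "g.json"
    graph.to_json(path)
    loaded = KnowledgeGraph.from_json(path)
    assert graph_statistics(loaded) == graph_statistics(graph)
    assert loaded.to_json() == graph.to_json()


def test_graphml_export_readable(tiny_store, tmp_path):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    path = tmp_path / "g.graphml"
    graph.write_graphml(path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == len(graph.nodes)
    assert g.number_of_edges() == len(graph.edges)


def test_protein_table_and_report(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    table = graph.protein_table()
    assert set(table["protein_id"]) == set(graph.protein_ids())
    report = graph.report_table()
    assert {"component", "term_id", "E", "S", "included"} <= set(report.columns)
    assert report["included"].any()


# ------------------------------------------------------------------ layout
def test_layout_angles_and_radii(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    positions = compute_layout(graph, style="nested", layers=7)
    assert set(positions) == set(graph.nodes)
    # all nodes of one layer equidistant from the shared centre
    by_radius: dict[float, list[str]] = {}
    for nid, (x, y) in positions.items():
        r = round(math.hypot(x, y), 6)
        by_radius.setdefault(r, []).append(nid)
    for r, members in by_radius.items():
        comps = {
            (graph.nodes[m].component,
             graph.nodes[m].role in ("query", "core_protein"))
            for m in members
        }
        # a radius never mixes components (protein layers split by role)
        assert len({c for c, _ in comps}) == 1 or r == 0.0
    # angular gaps equal within a layer
    diseases = sorted(graph.nodes_of("disease"), key=lambda nd: nd.node_id)
    if len(diseases) > 2:
        angles = sorted(
            math.atan2(positions[nd.node_id][1], positions[nd.node_id][0])
            for nd in diseases
        )
        gaps = {round(b - a, 9) for a, b in zip(angles, angles[1:])}
        assert len(gaps) == 1


def test_isolated_layout_separates_circles(tiny_store):
    graph = build_knowledge_graph(["disease:D1"], tiny_store)
    positions = compute_layout(graph, style="isolated", layers=4)
    xs = [x for x, _ in positions.values()]
    assert max(xs) - min(xs) > 2  # circles offset along x
    with pytest.raises(BuildError):
        compute_layout(graph, style="spiral")
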