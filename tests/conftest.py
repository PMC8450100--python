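from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from kgforge.chem import BioactivityRecord, Fingerprint, PredictedDTI
from kgforge.datastore import (
    CompoundRecord,
    Datastore,
    DrugRecord,
    PPIRecord,
    ProteinRecord,
    TermRecord,
)
from kgforge.synthetic import SynthParams, generate_datastore

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def assert_valid_graph(graph) -> None:
    """Structural invariants every finished knowledge graph must satisfy:
    vocabulary closure, evidence iff targets, one targets edge per pair,
    per-component k-caps, no dangling edges, no isolated non-query nodes."""
    from kgforge.kg_builder import RELATION_VOCABULARY

    for e in graph.edges.values():
        assert e.source in graph.nodes and e.target in graph.nodes
        pair = frozenset({graph.nodes[e.source].component,
                          graph.nodes[e.target].component})
        assert e.relation in RELATION_VOCABULARY.get(pair, frozenset()), (
            e.relation, sorted(pair))
        assert (e.evidence is not None) == (e.relation == "targets")
    target_pairs = [
        (e.source, e.target) for e in graph.edges.values()
        if e.relation == "targets"
    ]
    assert len(target_pairs) == len(set(target_pairs))
    for component in ("pathway", "disease", "phenotype", "drug", "compound"):
        enriched = graph.nodes_of(component, roles=("enriched",))
        assert len(enriched) <= graph.params.k(component)
    for nd in graph.nodes.values():
        if nd.role != "query":
            assert graph.degree(nd.node_id) > 0, nd.node_id


@pytest.fixture(scope="session")
def small_store():
    """Small synthetic datastore with planted hubs and scaffold clusters."""
    datastore, ground_truth = generate_datastore(SynthParams(rng_seed=7))
    return datastore, ground_truth


def make_tiny_store() -> Datastore:
    """Hand-built store whose every association is visible by eye.

    P0001–P0005 human reviewed, P0006 mouse, P0007 human unreviewed.
    Disease D1 annotates P1–P3, D2 annotates P1; pathway W1 = {P1, P2};
    phenotype H1 = {P2, P3}. D1 modulates W1 and associates with H1.
    Drug DRG1 (targets P1, P2; indication D1) cross-references compound
    CC1. Bioactivities give CC2 two strong targets, CC1/CC3 one each.
    """
    fp = lambda *bits: Fingerprint(on_bits=frozenset(bits), width=64)  # noqa: E731
    proteins = {
        "P0001": ProteinRecord("P0001", "GEN1", 9606, True,
                               disease_ids=("D1", "D2"), pathway_ids=("W1",)),
        "P0002": ProteinRecord("P0002", "GEN2", 9606, True,
                               disease_ids=("D1",), pathway_ids=("W1",),
                               phenotype_ids=("H1",)),
        "P0003": ProteinRecord("P0003", "GEN3", 9606, True,
                               disease_ids=("D1",), phenotype_ids=("H1",)),
        "P0004": ProteinRecord("P0004", "GEN4", 9606, True),
        "P0005": ProteinRecord("P0005", "GEN5", 9606, True),
        "P0006": ProteinRecord("P0006", "Gen6", 10090, True,
                               disease_ids=("D1",)),
        "P0007": ProteinRecord("P0007", "GEN7", 9606, False),
    }
    terms = {
        ("D1", "disease"): TermRecord("D1", "disease", "disease one",
                                      pathway_ids=("W1",),
                                      phenotype_ids=("H1",)),
        ("D2", "disease"): TermRecord("D2", "disease", "disease two"),
        ("W1", "pathway"): TermRecord("W1", "pathway", "pathway one"),
        ("H1", "phenotype"): TermRecord("H1", "phenotype", "phenotype one"),
    }
    ppis = [
        PPIRecord("P0001", "P0004", 0.9),
        PPIRecord("P0002", "P0004", 0.8),
        PPIRecord("P0004", "P0005", 0.7),
        PPIRecord("P0001", "P0006", 0.9),
    ]
    drugs = {
        "DRG1": DrugRecord("DRG1", "drug one", "approved",
                           target_protein_ids=("P0001", "P0002"),
                           indication_disease_ids=("D1",),
                           compound_xref="CC1"),
    }
    compounds = {
        "CC1": CompoundRecord("CC1", fp(1, 2, 3, 4), "compound one"),
        "CC2": CompoundRecord("CC2", fp(10, 11, 12, 13), "compound two"),
        "CC3": CompoundRecord("CC3", fp(20, 21, 22, 23), "compound three"),
    }
    bioactivities = [
        BioactivityRecord("CC2", "P0001", "IC50", 8.5),
        BioactivityRecord("CC2", "P0002", "Ki", 8.2),
        BioactivityRecord("CC3", "P0001", "EC50", 6.0),
        BioactivityRecord("CC1", "P0002", "IC50", 9.0),
        BioactivityRecord("CC1", "P0003", "IC50", 7.0),
    ]
    predicted = [
        PredictedDTI("CC3", "P0002", "deepscreen", 0.9),
        PredictedDTI("DRG1", "P0003", "mdeepred", 0.8),
    ]
    return Datastore(
        proteins=proteins,
        ppis=ppis,
        terms=terms,
        drugs=drugs,
        compounds=compounds,
        bioactivities=bioactivities,
        predicted_dtis=predicted,
    )


@pytest.fixture()
def tiny_store() -> Datastore:
    return make_tiny_store()
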