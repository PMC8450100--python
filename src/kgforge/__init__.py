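"""kgforge: query-driven heterogeneous biomedical knowledge graphs.

Build small, query-specific knowledge graphs (genes/proteins, diseases,
pathways, phenotypes, drugs, compounds) from flat-file collections, with
overrepresentation-based node filtering, structurally diverse compound
selection and evidence-prioritized drug/compound–target edges, plus the
diversity/stability analyses and a synthetic datastore generator.
"""

from .chem import (
    BioactivityRecord,
    ClusterAssignment,
    CompoundPool,
    Fingerprint,
    PredictedDTI,
    assemble_compound_pool,
    cluster_compounds,
    filter_bioactivities,
    pchembl_from_concentration,
    select_diverse_compounds,
    tanimoto,
)
from .datastore import (
    CompoundRecord,
    Datastore,
    DrugRecord,
    PPIRecord,
    ProteinRecord,
    TermRecord,
    build_annotation_index,
    load_datastore,
    write_datastore,
)
from .enrichment import (
    EnrichmentResult,
    enrichment_pvalue,
    enrichment_score,
    rank_component_terms,
    select_top_k,
)
from .kg_analysis import (
    FrequencyTestResult,
    IdentityRecord,
    graph_statistics,
    identity_matrix,
    node_identity,
    term_frequency_analysis,
)
from .kg_builder import (
    BuildParams,
    Edge,
    KnowledgeGraph,
    Node,
    QuerySpec,
    add_enriched_terms,
    attach_cross_component_edges,
    build_knowledge_graph,
    collect_core_proteins,
    compute_layout,
    expand_neighbours,
    incorporate_ligands,
    reconcile_edge_labels,
)
from .synthetic import SynthParams, generate_datastore, generate_query_set

__version__ = "0.1.0"


def filter_proteins_by_taxon(datastore, taxa, reviewed_only=True,
                             allow_unreviewed=()):
    """Functional alias for :meth:`Datastore.filter_proteins_by_taxon`."""
    return datastore.filter_proteins_by_taxon(
        taxa, reviewed_only=reviewed_only, allow_unreviewed=allow_unreviewed
    )


def filter_ppis_by_confidence(datastore, min_cross, min_within,
                              cross_predicate=None):
    """Functional alias for :meth:`Datastore.filter_ppis_by_confidence`."""
    return datastore.filter_ppis_by_confidence(
        min_cross, min_within, cross_predicate=cross_predicate
    )
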