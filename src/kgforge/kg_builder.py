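"""Query-driven assembly of heterogeneous biomedical knowledge graphs.

A build starts from one or more query terms (gene/protein, disease,
pathway, phenotype, drug or compound), collects the core proteins
directly associated with them, expands along protein–protein
interactions, then adds the top-k enriched pathways, phenotypes and
diseases, known drugs, structurally diverse bioactive compounds and
predicted interactions. Compound–target edges carry an evidence label
(approved > experimental > predicted) and conflicting sources collapse
onto the most reliable one. Everything is deterministic for a fixed
(query, datastore, params) triple.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import cos, pi, sin
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from . import chem
from .chem import select_diverse_compounds
from .datastore import Datastore, DatastoreError, TERM_COMPONENTS
from .enrichment import (
    EnrichmentResult,
    rank_component_terms,
    select_top_k,
)

logger = logging.getLogger(__name__)

COMPONENTS = ("protein", "pathway", "disease", "phenotype", "drug", "compound")

_PROTEIN_ALIASES = {"protein", "gene", "gene/protein"}

#: Legal relation labels per unordered endpoint-component pair.
RELATION_VOCABULARY: dict[frozenset, frozenset[str]] = {
    frozenset({"protein"}): frozenset({"interacts with", "is ortholog of"}),
    frozenset({"protein", "disease"}): frozenset({"is related to"}),
    frozenset({"drug", "protein"}): frozenset({"targets"}),
    frozenset({"compound", "protein"}): frozenset({"targets"}),
    frozenset({"protein", "pathway"}): frozenset({"is involved in"}),
    frozenset({"protein", "phenotype"}): frozenset({"is associated with"}),
    frozenset({"drug", "disease"}): frozenset({"indicates"}),
    frozenset({"disease", "pathway"}): frozenset({"modulates"}),
    frozenset({"disease", "phenotype"}): frozenset({"is associated with"}),
}

EVIDENCE_PRIORITY = {"approved": 0, "experimental": 1, "predicted": 2}


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class QuerySpec:
    """User query: a list of (component, identifier-or-name) pairs."""

    terms: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise BuildError("query must contain at least one term")
        norm = []
        for component, ident in self.terms:
            component = "protein" if component in _PROTEIN_ALIASES else component
            if component not in COMPONENTS:
                raise BuildError(f"unknown query component {component!r}")
            norm.append((component, ident))
        object.__setattr__(self, "terms", tuple(norm))

    @classmethod
    def parse(cls, specs: Iterable[str]) -> "QuerySpec":
        """Parse ``component:identifier`` strings (identifier may contain ':')."""
        terms = []
        for spec in specs:
            component, _, ident = spec.partition(":")
            if not ident:
                raise BuildError(f"malformed query term {spec!r}")
            terms.append((component.strip(), ident.strip()))
        return cls(terms=tuple(terms))


def _default_k() -> dict[str, int]:
    return {c: 10 for c in COMPONENTS}


@dataclass(frozen=True)
class BuildParams:
    """All tunables of a build; defaults mirror the deployed service."""

    k_per_component: Mapping[str, int] = field(default_factory=_default_k)
    taxa: tuple[int, ...] = (9606,)
    reviewed_only: bool = True
    allow_unreviewed: tuple[str, ...] = ()
    include_experimental: bool = True
    include_predictions: bool = True
    # PPI confidence floors (0 keeps everything; the COVID-style setting
    # is cross=0.35, within=0.6)
    min_ppi_cross: float = 0.0
    min_ppi_within: float = 0.0
    # compound pool assembly
    pool_lower: int = 1000
    pool_upper: int = 2500
    pool_start_cutoff: float = 8.0
    pool_floor: float = 5.0
    pool_step: float = 0.5
    pool_max_iter: int = 20
    # compound clustering
    cluster_threshold: float = 0.5
    cluster_method: str = "leader"
    # optional ligand significance gates (off by default)
    ligand_min_E: float | None = None
    ligand_max_S: float | None = None
    # phenotype ontology parent-child thinning
    phenotype_thinning: bool = False
    report_top: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        k = {c: 10 for c in COMPONENTS}
        k.update(dict(self.k_per_component))
        if any(v < 0 for v in k.values()):
            raise BuildError("all k values must be >= 0")
        object.__setattr__(self, "k_per_component", k)
        object.__setattr__(self, "taxa", tuple(int(t) for t in self.taxa))

    def k(self, component: str) -> int:
        return self.k_per_component[component]


@dataclass
class Node:
    node_id: str
    component: str
    role: str  # query | core_protein | neighbour_protein | enriched | merged_drug
    display_name: str = ""
    provenance: tuple[str, ...] = ()


@dataclass
class Edge:
    source: str
    target: str
    relation: str
    evidence: str | None = None  # approved | experimental | predicted
    weight: float | None = None

    def key(self) -> tuple[str, str, str, str]:
        # evidence is part of the identity until reconciliation collapses
        # multi-source target edges onto the best evidence
        return (self.source, self.target, self.relation, self.evidence or "")


class KnowledgeGraph:
    """Typed nodes plus evidence-labelled edges, with build provenance."""

    def __init__(self, query: QuerySpec, params: BuildParams):
        self.query = query
        self.params = params
        self.nodes: dict[str, Node] = {}
        self.edges: dict[tuple[str, str, str], Edge] = {}
        self.report: dict[str, list[EnrichmentResult]] = {}
        self.layout: dict[str, tuple[float, float]] | None = None

    # ------------------------------------------------------------- mutation
    def add_node(self, node: Node) -> Node:
        existing = self.nodes.get(node.node_id)
        if existing is not None:
            if existing.component != node.component:
                raise BuildError(
                    f"node id {node.node_id} reused across components "
                    f"{existing.component}/{node.component}"
                )
            return existing
        self.nodes[node.node_id] = node
        return node

    def add_edge(self, edge: Edge) -> None:
        if edge.source not in self.nodes or edge.target not in self.nodes:
            raise BuildError(
                f"dangling edge {edge.source}->{edge.target} ({edge.relation})"
            )
        pair = frozenset(
            {self.nodes[edge.source].component, self.nodes[edge.target].component}
        )
        legal = RELATION_VOCABULARY.get(pair, frozenset())
        if edge.relation not in legal:
            raise BuildError(
                f"relation {edge.relation!r} illegal for components {sorted(pair)}"
            )
        if (edge.evidence is not None) != (edge.relation == "targets"):
            raise BuildError(
                f"evidence must be present iff relation is 'targets' "
                f"({edge.source}->{edge.target} {edge.relation})"
            )
        self.edges.setdefault(edge.key(), edge)

    # ---------------------------------------------------------------- views
    def nodes_of(self, component: str, roles: Iterable[str] | None = None) -> list[Node]:
        roles = None if roles is None else set(roles)
        return [
            nd
            for _, nd in sorted(self.nodes.items())
            if nd.component == component and (roles is None or nd.role in roles)
        ]

    def protein_ids(self) -> list[str]:
        return [nd.node_id for nd in self.nodes_of("protein")]

    def degree(self, node_id: str) -> int:
        return sum(
            1 for e in self.edges.values() if node_id in (e.source, e.target)
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node_id, nd in sorted(self.nodes.items()):
            g.add_node(
                node_id,
                component=nd.component,
                role=nd.role,
                display_name=nd.display_name,
            )
        for key in sorted(self.edges):
            e = self.edges[key]
            g.add_edge(
                e.source,
                e.target,
                key=e.relation,
                relation=e.relation,
                evidence=e.evidence or "",
                weight=float("nan") if e.weight is None else e.weight,
            )
        return g

    # -------------------------------------------------------- serialization
    def to_json_dict(self) -> dict:
        return {
            "query": [list(t) for t in self.query.terms],
            "params": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.params).items()
                    if k != "k_per_component"
                },
                "k_per_component": dict(self.params.k_per_component),
            },
            "nodes": [
                {
                    "id": nd.node_id,
                    "component": nd.component,
                    "role": nd.role,
                    "display_name": nd.display_name,
                    "provenance": list(nd.provenance),
                }
                for _, nd in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "relation": e.relation,
                    "evidence": e.evidence,
                    "weight": e.weight,
                }
                for k, e in sorted(self.edges.items())
            ],
            "report": {
                component: [
                    {
                        "term_id": r.term_id,
                        "component": r.component,
                        "m": r.m,
                        "n": r.n,
                        "M": r.M,
                        "N": r.N,
                        "E": r.E,
                        "S": r.S,
                    }
                    for r in results
                ]
                for component, results in sorted(self.report.items())
            },
            "layout": (
                None
                if self.layout is None
                else {nid: list(xy) for nid, xy in sorted(self.layout.items())}
            ),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "KnowledgeGraph":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        params_raw = dict(payload.get("params", {}))
        for key in ("taxa", "allow_unreviewed"):
            if key in params_raw:
                params_raw[key] = tuple(params_raw[key])
        params = BuildParams(**params_raw) if params_raw else BuildParams()
        graph = cls(
            query=QuerySpec(tuple((c, i) for c, i in payload["query"])),
            params=params,
        )
        for nd in payload["nodes"]:
            graph.nodes[nd["id"]] = Node(
                node_id=nd["id"],
                component=nd["component"],
                role=nd["role"],
                display_name=nd.get("display_name", ""),
                provenance=tuple(nd.get("provenance", ())),
            )
        for ed in payload["edges"]:
            edge = Edge(
                source=ed["source"],
                target=ed["target"],
                relation=ed["relation"],
                evidence=ed.get("evidence"),
                weight=ed.get("weight"),
            )
            graph.edges[edge.key()] = edge
        for component, entries in payload.get("report", {}).items():
            graph.report[component] = [
                EnrichmentResult(
                    term_id=r["term_id"],
                    component=r.get("component", component),
                    m=r["m"], n=r["n"], M=r["M"], N=r["N"],
                    E=r["E"], S=r["S"],
                )
                for r in entries
            ]
        if payload.get("layout"):
            graph.layout = {
                nid: (xy[0], xy[1]) for nid, xy in payload["layout"].items()
            }
        return graph

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def protein_table(self) -> pd.DataFrame:
        """Protein-centric export: one row per gene/protein node."""
        rows = []
        for nd in self.nodes_of("protein"):
            partners: dict[str, list[str]] = {c: [] for c in COMPONENTS}
            for e in self.edges.values():
                if nd.node_id == e.source:
                    other = e.target
                elif nd.node_id == e.target:
                    other = e.source
                else:
                    continue
                partners[self.nodes[other].component].append(other)
            rows.append(
                {
                    "protein_id": nd.node_id,
                    "display_name": nd.display_name,
                    "role": nd.role,
                    **{
                        f"{c}_partners": "|".join(sorted(set(partners[c])))
                        for c in COMPONENTS
                    },
                }
            )
        return pd.DataFrame(rows)

    def report_table(self) -> pd.DataFrame:
        """Query report: per-component enrichment of the top-ranked terms."""
        rows = []
        present = set(self.nodes)
        for component in sorted(self.report):
            for r in self.report[component]:
                rows.append(
                    {
                        "component": component,
                        "term_id": r.term_id,
                        "m": r.m,
                        "M": r.M,
                        "E": r.E,
                        "S": r.S,
                        "included": r.term_id in present,
                    }
                )
        return pd.DataFrame(rows)


# -------------------------------------------------------------- resolution
def resolve_query_term(
    component: str, ident: str, datastore: Datastore
) -> str:
    """Resolve an identifier or name to a canonical id.

    Order: exact id, exact name, case-insensitive name; ambiguity is an
    error listing the candidates.
    """
    def pick(matches: list[str], what: str) -> str:
        uniq = sorted(set(matches))
        if len(uniq) > 1:
            raise BuildError(f"ambiguous {what} {ident!r}: candidates {uniq}")
        return uniq[0]

    if component == "protein":
        if ident in datastore.proteins:
            return ident
        exact = [p.protein_id for p in datastore.proteins.values()
                 if p.gene_symbol == ident]
        if exact:
            return pick(exact, "gene symbol")
        ci = [p.protein_id for p in datastore.proteins.values()
              if p.gene_symbol.casefold() == ident.casefold()]
        if ci:
            return pick(ci, "gene symbol")
    elif component in TERM_COMPONENTS:
        if (ident, component) in datastore.terms:
            return ident
        exact = [t.term_id for t in datastore.terms.values()
                 if t.component == component and t.name == ident]
        if exact:
            return pick(exact, f"{component} name")
        ci = [t.term_id for t in datastore.terms.values()
              if t.component == component and t.name.casefold() == ident.casefold()]
        if ci:
            return pick(ci, f"{component} name")
    elif component == "drug":
        if ident in datastore.drugs:
            return ident
        exact = [d.drug_id for d in datastore.drugs.values() if d.name == ident]
        if exact:
            return pick(exact, "drug name")
        ci = [d.drug_id for d in datastore.drugs.values()
              if d.name.casefold() == ident.casefold()]
        if ci:
            return pick(ci, "drug name")
    elif component == "compound":
        if ident in datastore.compounds:
            return ident
        exact = [c.compound_id for c in datastore.compounds.values()
                 if c.name == ident]
        if exact:
            return pick(exact, "compound name")
        ci = [c.compound_id for c in datastore.compounds.values()
              if c.name and c.name.casefold() == ident.casefold()]
        if ci:
            return pick(ci, "compound name")
    raise BuildError(f"unresolvable query term {component}:{ident}")


def _resolve_with_fallback(
    component: str,
    ident: str,
    view: Datastore,
    full_store: Datastore | None,
) -> str:
    """Resolve against the filtered view first, then the unfiltered store
    (a query term removed by taxon/reviewed filtering still anchors)."""
    try:
        return resolve_query_term(component, ident, view)
    except BuildError:
        if full_store is None:
            raise
        return resolve_query_term(component, ident, full_store)


# ------------------------------------------------------------------- steps
def collect_core_proteins(
    query: QuerySpec,
    datastore: Datastore,
    full_store: Datastore | None = None,
) -> tuple[set[str], dict[str, set[str]]]:
    """Directly associated proteins per query term, plus their union.

    A gene/protein term contributes itself; a disease/pathway/phenotype
    term its annotated proteins; a drug its targets; a compound its
    single-protein bioactivity and predicted targets. The datastore is
    expected to be pre-filtered (taxon/reviewed), so contributions are
    automatically restricted to visible proteins.
    """
    provenance: dict[str, set[str]] = {}
    for component, ident in query.terms:
        resolved = _resolve_with_fallback(component, ident, datastore, full_store)
        if component == "protein":
            # a filtered-out queried protein anchors the graph but
            # contributes no core member
            contribution = {resolved} if resolved in datastore.proteins else set()
        elif component in TERM_COMPONENTS:
            contribution = set(
                datastore.annotation_index[component].get(resolved, frozenset())
            )
        elif component == "drug":
            contribution = set(
                datastore.annotation_index["drug"].get(resolved, frozenset())
            )
        else:  # compound
            contribution = set(
                datastore.annotation_index["compound-experimental"].get(
                    resolved, frozenset()
                )
            ) | set(
                datastore.annotation_index["compound-predicted"].get(
                    resolved, frozenset()
                )
            )
        if not contribution:
            logger.warning("query term %s:%s has no associated proteins",
                           component, ident)
        provenance[f"{component}:{resolved}"] = contribution
    core = set().union(*provenance.values()) if provenance else set()
    return core, provenance


def expand_neighbours(
    core: Iterable[str], datastore: Datastore, k: int
) -> list[EnrichmentResult]:
    """Top-k first neighbours of the core, scored by enrichment.

    Each candidate neighbour is treated as a term whose association set is
    its PPI partner list: m = partners inside the core, n = |core|,
    M = total partners, N = proteins with at least one PPI.
    """
    core = frozenset(core)
    candidates = sorted(
        {
            partner
            for pid in core
            for partner in datastore.ppi_index.get(pid, frozenset())
        }
        - core
    )
    if not candidates:
        return []
    index = {c: datastore.ppi_index[c] for c in candidates}
    N = datastore.component_totals["ppi"]
    ranked = rank_component_terms(core, index, N=N, component="protein")
    return select_top_k(ranked, k)


def add_enriched_terms(
    graph: KnowledgeGraph,
    component: str,
    datastore: Datastore,
    k: int,
    exclusions: Iterable[str] = (),
) -> KnowledgeGraph:
    """Add the component's top-k enriched terms and their association edges."""
    N = datastore.component_totals[component]
    if N == 0:
        return graph
    proteins = frozenset(graph.protein_ids())
    index = datastore.annotation_index[component]
    ranked = rank_component_terms(
        proteins, index, N=N, component=component, exclusions=exclusions
    )
    graph.report[component] = ranked[: graph.params.report_top]

    admit = None
    if component == "phenotype" and graph.params.phenotype_thinning:
        admit = _parent_child_thinning(datastore)

    relation = {
        "disease": "is related to",
        "pathway": "is involved in",
        "phenotype": "is associated with",
    }[component]
    for result in select_top_k(ranked, k, admit_predicate=admit):
        term = datastore.term(result.term_id, component)
        graph.add_node(
            Node(
                node_id=result.term_id,
                component=component,
                role="enriched",
                display_name=term.name if term else result.term_id,
            )
        )
        for pid in sorted(index[result.term_id] & proteins):
            graph.add_edge(Edge(source=pid, target=result.term_id,
                                relation=relation))
    return graph


def _parent_child_thinning(datastore: Datastore):
    """Admit predicate rejecting a term whose parent or child was selected."""

    def parents(term_id: str) -> frozenset[str]:
        term = datastore.term(term_id, "phenotype")
        return frozenset(term.parent_ids) if term else frozenset()

    def admit(candidate: EnrichmentResult,
              selected: list[EnrichmentResult]) -> bool:
        cand_parents = parents(candidate.term_id)
        for prior in selected:
            if prior.term_id in cand_parents:
                return False
            if candidate.term_id in parents(prior.term_id):
                return False
        return True

    return admit


def _ligand_gate(params: BuildParams):
    min_E, max_S = params.ligand_min_E, params.ligand_max_S

    def passes(r: EnrichmentResult) -> bool:
        if min_E is not None and r.E <= min_E:
            return False
        if max_S is not None and r.S >= max_S:
            return False
        return True

    return passes


def _compound_to_drug(datastore: Datastore) -> dict[str, str]:
    return {
        d.compound_xref: d.drug_id
        for d in sorted(datastore.drugs.values(), key=lambda d: d.drug_id)
        if d.compound_xref
    }


def incorporate_ligands(
    graph: KnowledgeGraph, datastore: Datastore, params: BuildParams
) -> KnowledgeGraph:
    """Add enriched drugs, diverse bioactive compounds and predicted DTIs.

    Drugs carry approved-evidence target edges. The experimental compound
    pool is assembled with the iterative pChEMBL-cutoff search, ranked by
    enrichment and thinned to one compound per structural cluster;
    predicted ligands follow the same route. A selected compound that
    cross-references a drug is represented by the drug node (merged).
    """
    proteins = frozenset(graph.protein_ids())
    gate = _ligand_gate(params)
    xref = _compound_to_drug(datastore)

    # (a) approved drugs
    drug_index = datastore.annotation_index["drug"]
    N_drug = datastore.component_totals["drug"]
    query_ids = {ident for comp, ident in graph.query.terms if comp == "drug"}
    if N_drug and proteins:
        ranked = rank_component_terms(
            proteins, drug_index, N=N_drug, component="drug",
            exclusions=query_ids,
        )
        graph.report["drug"] = ranked[: params.report_top]
        for result in select_top_k([r for r in ranked if gate(r)],
                                   params.k("drug")):
            drug = datastore.drugs[result.term_id]
            graph.add_node(
                Node(node_id=drug.drug_id, component="drug", role="enriched",
                     display_name=drug.name)
            )
            for pid in sorted(drug_index[drug.drug_id] & proteins):
                graph.add_edge(
                    Edge(source=drug.drug_id, target=pid, relation="targets",
                         evidence="approved")
                )

    selected_clusters: set[str] = set()
    compound_slots = params.k("compound")

    def ligand_node(ligand_id: str) -> str:
        """Place the node for a selected ligand, merging onto a drug
        node when a cross-reference exists; returns the node id used."""
        if ligand_id in datastore.drugs:
            node_id, name = ligand_id, datastore.drugs[ligand_id].name
            graph.add_node(
                Node(node_id=node_id, component="drug", role="merged_drug",
                     display_name=name)
            )
        elif ligand_id in xref:
            drug = datastore.drugs[xref[ligand_id]]
            node_id = drug.drug_id
            existing = graph.nodes.get(node_id)
            if existing is None:
                graph.add_node(
                    Node(node_id=node_id, component="drug", role="merged_drug",
                         display_name=drug.name)
                )
        else:
            node_id = ligand_id
            comp = datastore.compounds.get(ligand_id)
            graph.add_node(
                Node(node_id=node_id, component="compound", role="enriched",
                     display_name=comp.name if comp else ligand_id)
            )
        return node_id

    global_clusters = datastore.compound_clusters(
        threshold=params.cluster_threshold, method=params.cluster_method
    )

    def fingerprint_clusters(ligand_ids: Sequence[str]) -> Mapping[str, str]:
        """Store-wide cluster ids; ligands without a fingerprint (e.g.
        drug-only predicted entries) fall back to singleton clusters."""
        membership = {}
        for cid in ligand_ids:
            membership[cid] = global_clusters.membership.get(
                cid, f"singleton:{cid}"
            )
        return membership

    # (b) experimental bioactive compounds
    if params.include_experimental and proteins:
        pool = chem.assemble_compound_pool(
            datastore.bioactivities,
            proteins,
            taxa=params.taxa,
            lower=params.pool_lower,
            upper=params.pool_upper,
            start_cutoff=params.pool_start_cutoff,
            floor=params.pool_floor,
            step=params.pool_step,
            max_iter=params.pool_max_iter,
        )
        if pool.distinct_compounds:
            # M counts a compound's whole single-protein target space at
            # the final cutoff, not just targets inside the graph
            all_targets: dict[str, set[str]] = {}
            for r in chem.filter_bioactivities(
                datastore.bioactivities, taxa=params.taxa,
                pchembl_min=pool.final_cutoff,
            ):
                if r.target_protein_id in datastore.proteins:
                    all_targets.setdefault(r.compound_id, set()).add(
                        r.target_protein_id
                    )
            index = {
                cid: frozenset(all_targets.get(cid, set()))
                for cid in sorted(pool.distinct_compounds)
            }
            N_comp = datastore.component_totals["compound-experimental"]
            ranked = rank_component_terms(
                proteins, index, N=N_comp, component="compound",
            )
            graph.report["compound"] = ranked[: params.report_top]
            ranked_ids = [r.term_id for r in ranked if gate(r)]
            membership = fingerprint_clusters(ranked_ids)
            chosen = select_diverse_compounds(
                ranked_ids, membership, compound_slots, selected_clusters
            )
            pool_targets: dict[str, dict[str, float]] = {}
            for r in pool.records:
                best = pool_targets.setdefault(r.compound_id, {})
                best[r.target_protein_id] = max(
                    best.get(r.target_protein_id, 0.0), r.pchembl or 0.0
                )
            for cid in chosen:
                selected_clusters.add(membership[cid])
                node_id = ligand_node(cid)
                for pid in sorted(set(pool_targets.get(cid, {})) & proteins):
                    graph.add_edge(
                        Edge(source=node_id, target=pid, relation="targets",
                             evidence="experimental",
                             weight=pool_targets[cid][pid])
                    )
            compound_slots -= len(chosen)

    # (c) predicted drug/compound–target interactions
    if params.include_predictions and proteins and compound_slots > 0:
        pred_index = datastore.annotation_index["compound-predicted"]
        N_pred = datastore.component_totals["compound-predicted"]
        if N_pred:
            ranked = rank_component_terms(
                proteins, pred_index, N=N_pred, component="compound",
            )
            graph.report.setdefault("compound-predicted", ranked[: params.report_top])
            ranked_ids = [r.term_id for r in ranked if gate(r)]
            membership = fingerprint_clusters(ranked_ids)
            chosen = select_diverse_compounds(
                ranked_ids, membership, compound_slots, selected_clusters
            )
            scores: dict[tuple[str, str], float | None] = {}
            for r in datastore.predicted_dtis:
                scores[(r.compound_or_drug_id, r.target_protein_id)] = r.score
            for cid in chosen:
                selected_clusters.add(membership[cid])
                node_id = ligand_node(cid)
                for pid in sorted(pred_index[cid] & proteins):
                    graph.add_edge(
                        Edge(source=node_id, target=pid, relation="targets",
                             evidence="predicted",
                             weight=scores.get((cid, pid)))
                    )
    return graph


def reconcile_edge_labels(
    graph: KnowledgeGraph, datastore: Datastore | None = None
) -> KnowledgeGraph:
    """Collapse multi-evidence target edges and run the edge-addition pass.

    For every (ligand, protein) pair only the highest-priority evidence
    survives (approved > experimental > predicted). Then drug nodes gain
    experimental edges for bioactivities of their cross-referenced
    compound against graph proteins not already covered, and drugs and
    compounds gain predicted edges likewise. Idempotent.
    """
    by_pair: dict[tuple[str, str], list[Edge]] = {}
    others: list[Edge] = []
    for key in sorted(graph.edges):
        e = graph.edges[key]
        if e.relation == "targets":
            by_pair.setdefault((e.source, e.target), []).append(e)
        else:
            others.append(e)
    merged: dict[tuple[str, str, str], Edge] = {e.key(): e for e in others}
    for pair in sorted(by_pair):
        variants = by_pair[pair]
        best = min(variants, key=lambda e: EVIDENCE_PRIORITY[e.evidence])
        merged[best.key()] = best
    graph.edges = merged

    if datastore is not None:
        proteins = frozenset(graph.protein_ids())
        covered = {
            (e.source, e.target)
            for e in graph.edges.values()
            if e.relation == "targets"
        }
        drug_to_compound = {
            d.drug_id: d.compound_xref
            for d in datastore.drugs.values()
            if d.compound_xref
        }
        exp_targets: dict[str, dict[str, float]] = {}
        for r in chem.filter_bioactivities(
            datastore.bioactivities, taxa=graph.params.taxa,
            pchembl_min=graph.params.pool_floor,
        ):
            best = exp_targets.setdefault(r.compound_id, {})
            best[r.target_protein_id] = max(
                best.get(r.target_protein_id, 0.0), r.pchembl or 0.0
            )
        pred_targets: dict[str, dict[str, float | None]] = {}
        for r in datastore.predicted_dtis:
            pred_targets.setdefault(r.compound_or_drug_id, {})[
                r.target_protein_id
            ] = r.score

        for nd in graph.nodes_of("drug"):
            cid = drug_to_compound.get(nd.node_id)
            if cid is not None and graph.params.include_experimental:
                for pid, w in sorted(exp_targets.get(cid, {}).items()):
                    if pid in proteins and (nd.node_id, pid) not in covered:
                        graph.add_edge(
                            Edge(source=nd.node_id, target=pid,
                                 relation="targets", evidence="experimental",
                                 weight=w)
                        )
                        covered.add((nd.node_id, pid))
        if graph.params.include_predictions:
            for nd in graph.nodes_of("drug") + graph.nodes_of("compound"):
                pred_ids = [nd.node_id]
                if nd.node_id in drug_to_compound:
                    pred_ids.append(drug_to_compound[nd.node_id])
                for pred_id in pred_ids:
                    for pid, score in sorted(
                        pred_targets.get(pred_id, {}).items()
                    ):
                        if pid in proteins and (nd.node_id, pid) not in covered:
                            graph.add_edge(
                                Edge(source=nd.node_id, target=pid,
                                     relation="targets", evidence="predicted",
                                     weight=score)
                            )
                            covered.add((nd.node_id, pid))
    return graph


def attach_cross_component_edges(
    graph: KnowledgeGraph, datastore: Datastore
) -> KnowledgeGraph:
    """Add drug–disease, disease–pathway and disease–phenotype edges
    wherever both endpoints are present and the datastore records the
    relation."""
    present = graph.nodes
    for nd in graph.nodes_of("drug"):
        drug = datastore.drugs.get(nd.node_id)
        if drug is None:
            continue
        for disease_id in sorted(drug.indication_disease_ids):
            if disease_id in present and present[disease_id].component == "disease":
                graph.add_edge(
                    Edge(source=nd.node_id, target=disease_id,
                         relation="indicates")
                )
    for nd in graph.nodes_of("disease"):
        term = datastore.term(nd.node_id, "disease")
        if term is None:
            continue
        for pw in sorted(term.pathway_ids):
            if pw in present and present[pw].component == "pathway":
                graph.add_edge(
                    Edge(source=nd.node_id, target=pw, relation="modulates")
                )
        for ph in sorted(term.phenotype_ids):
            if ph in present and present[ph].component == "phenotype":
                graph.add_edge(
                    Edge(source=nd.node_id, target=ph,
                         relation="is associated with")
                )
    return graph


def prune_isolated_nodes(graph: KnowledgeGraph) -> KnowledgeGraph:
    """Drop degree-0 non-query nodes; query anchors always stay."""
    degree: dict[str, int] = {nid: 0 for nid in graph.nodes}
    for e in graph.edges.values():
        degree[e.source] += 1
        degree[e.target] += 1
    graph.nodes = {
        nid: nd
        for nid, nd in graph.nodes.items()
        if degree[nid] > 0 or nd.role == "query"
    }
    return graph


def build_knowledge_graph(
    query: QuerySpec | Sequence[str],
    datastore: Datastore,
    params: BuildParams | None = None,
) -> KnowledgeGraph:
    """Run the full construction workflow for one query."""
    if not isinstance(query, QuerySpec):
        query = QuerySpec.parse(query)
    params = params or BuildParams()
    view = datastore.filter_proteins_by_taxon(
        params.taxa, reviewed_only=params.reviewed_only,
        allow_unreviewed=params.allow_unreviewed,
    )
    if params.min_ppi_cross > 0 or params.min_ppi_within > 0:
        view = view.filter_ppis_by_confidence(
            params.min_ppi_cross, params.min_ppi_within
        )

    graph = KnowledgeGraph(query=query, params=params)
    core, provenance = collect_core_proteins(query, view, full_store=datastore)
    if not core and not any(c == "protein" for c, _ in query.terms):
        if all(not v for v in provenance.values()):
            raise BuildError("query resolved but no core proteins remain "
                             "after filtering")

    # query anchors are always nodes
    resolved_query: list[tuple[str, str]] = []
    for component, ident in query.terms:
        resolved = _resolve_with_fallback(component, ident, view, datastore)
        resolved_query.append((component, resolved))
        display = ident
        if component == "protein" and resolved in datastore.proteins:
            display = datastore.proteins[resolved].gene_symbol
        elif component in TERM_COMPONENTS:
            term = view.term(resolved, component)
            display = term.name if term else ident
        elif component == "drug" and resolved in view.drugs:
            display = view.drugs[resolved].name
        graph.add_node(
            Node(node_id=resolved, component=component, role="query",
                 display_name=display, provenance=("query",))
        )

    for pid in sorted(core):
        if pid not in graph.nodes:
            rec = view.proteins[pid]
            graph.add_node(
                Node(node_id=pid, component="protein", role="core_protein",
                     display_name=rec.gene_symbol)
            )

    for result in expand_neighbours(core, view, params.k("protein")):
        rec = view.proteins[result.term_id]
        graph.add_node(
            Node(node_id=result.term_id, component="protein",
                 role="neighbour_protein", display_name=rec.gene_symbol)
        )

    # intra-protein edges for every stored PPI between graph proteins
    graph_proteins = frozenset(graph.protein_ids())
    for rec in view.ppis:
        if rec.protein_a in graph_proteins and rec.protein_b in graph_proteins:
            a, b = rec.pair
            graph.add_edge(
                Edge(source=a, target=b, relation="interacts with",
                     weight=rec.confidence)
            )

    query_terms_by_component: dict[str, set[str]] = {}
    for component, resolved in resolved_query:
        query_terms_by_component.setdefault(component, set()).add(resolved)
    for component in ("pathway", "phenotype", "disease"):
        add_enriched_terms(
            graph, component, view, params.k(component),
            exclusions=query_terms_by_component.get(component, set()),
        )
        # query-term association edges (anchor terms keep their context)
        for term_id in sorted(query_terms_by_component.get(component, set())):
            index = view.annotation_index[component]
            relation = {
                "disease": "is related to",
                "pathway": "is involved in",
                "phenotype": "is associated with",
            }[component]
            for pid in sorted(index.get(term_id, frozenset()) & graph_proteins):
                graph.add_edge(Edge(source=pid, target=term_id,
                                    relation=relation))

    incorporate_ligands(graph, view, params)
    # queried drugs keep their approved target edges
    for drug_id in sorted(query_terms_by_component.get("drug", set())):
        targets = view.annotation_index["drug"].get(drug_id, frozenset())
        for pid in sorted(targets & graph_proteins):
            graph.add_edge(Edge(source=drug_id, target=pid, relation="targets",
                                evidence="approved"))
    reconcile_edge_labels(graph, view)
    attach_cross_component_edges(graph, view)
    prune_isolated_nodes(graph)
    return graph


# ------------------------------------------------------------------ layout
_SEVEN_LAYERS = (
    ("protein", ("query", "core_protein")),
    ("protein", ("neighbour_protein",)),
    ("pathway", None),
    ("disease", None),
    ("phenotype", None),
    ("drug", None),
    ("compound", None),
)
_FOUR_LAYERS = (
    (("protein",), None),
    (("pathway",), None),
    (("disease", "phenotype"), None),
    (("drug", "compound"), None),
)


def compute_layout(
    graph: KnowledgeGraph, style: str = "nested", layers: int = 7
) -> dict[str, tuple[float, float]]:
    """Concentric (nested) or side-by-side (isolated) circular coordinates.

    Each layer's nodes are evenly spaced by angle in deterministic order
    (component, then node id). Nested layers share a centre with strictly
    increasing radii; isolated layers get disjoint unit circles.
    """
    if style not in ("nested", "isolated"):
        raise BuildError(f"unknown layout style {style!r}")
    if layers not in (4, 7):
        raise BuildError("layers must be 4 or 7")
    if not graph.nodes:
        raise BuildError("cannot lay out an empty graph")

    layer_nodes: list[list[Node]] = []
    if layers == 7:
        for component, roles in _SEVEN_LAYERS:
            members = graph.nodes_of(component, roles)
            if component == "protein" and roles and "query" in roles:
                # non-protein query nodes live with their own component
                members = [nd for nd in members if nd.component == "protein"]
            layer_nodes.append(members)
    else:
        for components, _ in _FOUR_LAYERS:
            members = [
                nd
                for c in components
                for nd in graph.nodes_of(c)
            ]
            members.sort(key=lambda nd: (nd.component, nd.node_id))
            layer_nodes.append(members)

    positions: dict[str, tuple[float, float]] = {}
    for layer_idx, members in enumerate(layer_nodes):
        if not members:
            continue
        if style == "nested":
            cx, cy, radius = 0.0, 0.0, float(layer_idx + 1)
        else:
            cx, cy, radius = 3.0 * layer_idx, 0.0, 1.0
        n = len(members)
        for i, nd in enumerate(members):
            angle = 2.0 * pi * i / n
            positions[nd.node_id] = (
                cx + radius * cos(angle),
                cy + radius * sin(angle),
            )
    graph.layout = positions
    return positions
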