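"""Diversity and stability analyses over collections of knowledge graphs.

Two complementary measurements: pairwise node identity between graphs
(how much content two queries share) and per-term observed-vs-expected
presence frequency (whether promiscuous hub terms sneak into graphs more
often than their connectivity predicts). A term D appearing in g of G
graphs has observed frequency g/G; its expected frequency under the
null of connectivity-proportional inclusion is t * M_D / M_sum, where t
is the per-graph node budget of D's component, M_D the number of
proteins associated with D, and M_sum the total number of
protein–term associations in that component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest, fisher_exact

from .datastore import Datastore
from .kg_builder import KnowledgeGraph


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class IdentityRecord:
    graph_a: str
    graph_b: str
    shared_nodes: int
    identity_pct: float
    mode: str


@dataclass(frozen=True)
class FrequencyTestResult:
    term_id: str
    component: str
    g: int
    G: int
    observed_freq: float
    expected_freq: float
    p_value: float
    direction: str  # under | over | none


def _node_keys(graph: KnowledgeGraph) -> frozenset[tuple[str, str]]:
    return frozenset((nd.node_id, nd.component) for nd in graph.nodes.values())


def node_identity(
    a: KnowledgeGraph,
    b: KnowledgeGraph,
    mode: str = "jaccard",
    name_a: str = "a",
    name_b: str = "b",
) -> IdentityRecord:
    """Percentage of shared nodes (matched by id and component).

    The denominator convention is recorded with the value: ``jaccard``
    (union, default), ``min`` (smaller graph) or ``mean`` (average size).
    """
    keys_a, keys_b = _node_keys(a), _node_keys(b)
    if not keys_a and not keys_b:
        raise AnalysisError("cannot compare two empty graphs")
    shared = len(keys_a & keys_b)
    if mode == "jaccard":
        denom = len(keys_a | keys_b)
    elif mode == "min":
        denom = min(len(keys_a), len(keys_b)) or 1
    elif mode == "mean":
        denom = (len(keys_a) + len(keys_b)) / 2
    else:
        raise AnalysisError(f"unknown identity mode {mode!r}")
    return IdentityRecord(
        graph_a=name_a,
        graph_b=name_b,
        shared_nodes=shared,
        identity_pct=100.0 * shared / denom,
        mode=mode,
    )


def identity_matrix(
    graphs: Mapping[str, KnowledgeGraph], mode: str = "jaccard"
) -> list[IdentityRecord]:
    """All pairwise identities, deterministic order."""
    names = sorted(graphs)
    return [
        node_identity(graphs[a], graphs[b], mode=mode, name_a=a, name_b=b)
        for i, a in enumerate(names)
        for b in names[i + 1:]
    ]


def term_frequency_analysis(
    graphs: Sequence[KnowledgeGraph],
    datastore: Datastore,
    terms: Iterable[tuple[str, str]],
    t: int,
    alpha: float = 0.05,
    method: str = "fisher",
) -> list[FrequencyTestResult]:
    """Observed vs expected presence frequency for selected terms.

    ``terms`` is (term_id, component) pairs; ``t`` is the per-graph node
    budget (the k used at build time) of each term's component. The
    default test is a one-tailed Fisher's exact test on the pseudo-table
    [[g, G-g], [round(G*expected), G-round(G*expected)]]; ``method="binomial"``
    instead tests g ~ Binomial(G, expected). Directions are assigned only
    below ``alpha``.
    """
    if not graphs:
        raise AnalysisError("no graphs to analyse")
    G = len(graphs)
    presence = [_node_keys(g) for g in graphs]
    results = []
    for term_id, component in terms:
        index = datastore.annotation_index[component]
        M_D = len(index.get(term_id, frozenset()))
        M_sum = sum(len(v) for v in index.values())
        expected = t * M_D / M_sum if M_sum else 0.0
        if expected > 1.0:
            expected = 1.0  # clamped: budget exceeds component supply
        g = sum(1 for keys in presence if (term_id, component) in keys)
        observed = g / G
        if method == "fisher":
            exp_count = round(G * expected)
            table = [[g, G - g], [exp_count, G - exp_count]]
            alternative = "less" if observed < expected else "greater"
            p = float(fisher_exact(table, alternative=alternative).pvalue)
        elif method == "binomial":
            alternative = "less" if observed < expected else "greater"
            prob = min(max(expected, 0.0), 1.0)
            p = float(binomtest(g, G, prob, alternative=alternative).pvalue)
        else:
            raise AnalysisError(f"unknown method {method!r}")
        if p < alpha and observed < expected:
            direction = "under"
        elif p < alpha and observed > expected:
            direction = "over"
        else:
            direction = "none"
        results.append(
            FrequencyTestResult(
                term_id=term_id,
                component=component,
                g=g,
                G=G,
                observed_freq=observed,
                expected_freq=expected,
                p_value=p,
                direction=direction,
            )
        )
    return results


def graph_statistics(graph: KnowledgeGraph) -> dict[str, int]:
    """Census: node counts per component and role, edge counts per
    relation and evidence."""
    census: dict[str, int] = {}
    for nd in graph.nodes.values():
        census[f"nodes.{nd.component}"] = census.get(f"nodes.{nd.component}", 0) + 1
        census[f"roles.{nd.role}"] = census.get(f"roles.{nd.role}", 0) + 1
    for e in graph.edges.values():
        key = f"edges.{e.relation.replace(' ', '_')}"
        census[key] = census.get(key, 0) + 1
        if e.evidence:
            census[f"evidence.{e.evidence}"] = (
                census.get(f"evidence.{e.evidence}", 0) + 1
            )
    census["nodes.total"] = len(graph.nodes)
    census["edges.total"] = len(graph.edges)
    return census
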