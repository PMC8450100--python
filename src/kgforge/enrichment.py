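"""Overrepresentation scoring used at every node-filtering step.

For a candidate term D and a growing graph W the enrichment score is

    E = (m^2 / n) / (M / N)

where m is the number of gene/protein nodes of W associated with D, n the
total number of gene/protein nodes in W, M the number of proteins in the
whole (filtered) datastore associated with D, and N the number of
proteins carrying at least one association in D's component. Squaring m
(the departure from the classical hypergeometric fold enrichment) breaks
ties between terms of similar fold enrichment in favour of the one with
more graph connections, while the division by M suppresses promiscuous
hub terms. Significance S is the hypergeometric upper tail (one-tailed
Fisher's exact test); it is reported but never used for selection —
filtering keeps the top-k terms by E alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from scipy.stats import hypergeom


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment against a growing graph."""

    term_id: str
    component: str
    m: int  # graph proteins associated with the term
    n: int  # gene/protein nodes in the graph
    M: int  # datastore proteins associated with the term
    N: int  # component population size
    E: float
    S: float

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.n, self.M) and self.M <= self.N):
            raise EnrichmentError(
                f"inconsistent counts m={self.m} n={self.n} M={self.M} N={self.N}"
            )


def enrichment_score(m: int, n: int, M: int, N: int) -> float:
    """(m^2/n) / (M/N); zero when the term or graph has nothing to offer."""
    _check_args(m, n, M, N)
    if n == 0 or M == 0:
        return 0.0
    return (m * m / n) / (M / N)


def enrichment_pvalue(m: int, n: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric probability of seeing >= m associated
    proteins in a draw of n from a population of N containing M."""
    _check_args(m, n, M, N)
    if m == 0 or n == 0 or M == 0:
        return 1.0
    # P(X >= m) for X ~ Hypergeom(N, M, n)
    return float(hypergeom.sf(m - 1, N, M, n))


def _check_args(m: int, n: int, M: int, N: int) -> None:
    if N <= 0:
        raise EnrichmentError("empty component: N must be > 0")
    if n < 0 or M < 0 or m < 0:
        raise EnrichmentError("counts must be non-negative")
    if m > min(n, M):
        raise EnrichmentError(f"m={m} exceeds min(n={n}, M={M})")
    if M > N or n > N:
        raise EnrichmentError(f"M={M} and n={n} must not exceed N={N}")


def rank_component_terms(
    graph_proteins: Iterable[str],
    index: Mapping[str, frozenset[str] | set[str]],
    N: int,
    component: str = "",
    exclusions: Iterable[str] = (),
) -> list[EnrichmentResult]:
    """Score every candidate term with at least one graph association and
    return them in deterministic rank order.

    Order: descending E, then ascending S, then descending m, then
    lexicographic term id.
    """
    proteins = frozenset(graph_proteins)
    excluded = frozenset(exclusions)
    n = len(proteins)
    results: list[EnrichmentResult] = []
    for term_id in sorted(index):
        if term_id in excluded:
            continue
        members = index[term_id]
        m = len(proteins & members)
        if m == 0:
            continue
        M = len(members)
        # annotations can stretch beyond the scored population when the
        # graph mixes filter scopes; clamp defensively
        M_eff = min(M, N)
        n_eff = min(n, N)
        m_eff = min(m, n_eff, M_eff)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                component=component,
                m=m_eff,
                n=n_eff,
                M=M_eff,
                N=N,
                E=enrichment_score(m_eff, n_eff, M_eff, N),
                S=enrichment_pvalue(m_eff, n_eff, M_eff, N),
            )
        )
    results.sort(key=lambda r: (-r.E, r.S, -r.m, r.term_id))
    return results


def select_top_k(
    ranked: Sequence[EnrichmentResult],
    k: int,
    admit_predicate: Callable[[EnrichmentResult, list[EnrichmentResult]], bool]
    | None = None,
) -> list[EnrichmentResult]:
    """First k admitted entries in rank order.

    ``admit_predicate(candidate, admitted_so_far)`` can veto candidates
    (used for compound cluster exclusion and ontology parent–child
    thinning); significance is deliberately not a criterion.
    """
    if k < 0:
        raise EnrichmentError("k must be >= 0")
    selected: list[EnrichmentResult] = []
    for result in ranked:
        if len(selected) >= k:
            break
        if admit_predicate is None or admit_predicate(result, selected):
            selected.append(result)
    return selected
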