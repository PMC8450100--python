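# Methods

## The construction model

A knowledge graph is assembled around gene/protein entries in a fixed
order. Given a query (one or more terms of the six components —
gene/protein, disease, pathway, phenotype, drug, compound):

1. **Core proteins.** Each query term contributes its directly
   associated proteins (a gene/protein contributes itself, a disease or
   phenotype its annotated proteins, a pathway its members, a drug its
   targets, a compound its measured and predicted targets); multi-term
   queries take the union. The contribution is restricted by the active
   taxon filter (default: human, NCBI 9606) and, by default, to
   reviewed entries, with an accession allow-list to re-admit specific
   unreviewed entries when needed.
2. **Neighbour expansion.** First neighbours of the core via PPIs are
   scored with the enrichment statistic (each candidate's "annotation
   set" is its PPI partner list; the population N is the number of
   proteins with at least one PPI) and the top k enter.
3. **Enriched terms.** Pathways, phenotypes and diseases are ranked
   against the full protein set (core + neighbours, equally weighted)
   and their top k added with association edges. Query terms are
   excluded from the rankings, so a disease query cannot "rediscover"
   itself; it is always retained as an anchor node regardless of
   degree.
4. **Ligands.** Drugs are ranked by enrichment over their target sets
   and added with approved-evidence target edges. Experimental
   compounds pass the bioactivity filter and the iterative cutoff pool
   (below), are ranked by enrichment, and enter one-per-structural-
   cluster; predicted ligands follow the same route and fill whatever
   remains of the shared per-component compound budget, so the
   compound cap holds across both evidence routes. A selected compound
   that cross-references a drug is represented by the drug node
   (merged, typed drug).
5. **Edge reconciliation.** For every ligand–protein pair the highest
   priority evidence wins (approved > experimental > predicted). An
   edge-addition pass then surfaces additional experimental
   bioactivities of drug-linked compounds and additional predictions
   for drugs and compounds, against graph proteins only. The pass is
   idempotent.
6. **Cross-component edges.** drug→disease (indicates), disease→pathway
   (modulates) and disease→phenotype (is associated with) edges are
   added wherever both endpoints exist and the store records the
   relation.
7. **Pruning.** Degree-0 non-query nodes are removed.

Every step iterates in sorted order, so the serialized graph is a pure
function of (query, datastore, parameters); the recorded seed exists
for interface completeness — no stage of the build itself draws random
numbers.

### Enrichment statistic

E = (m²/n)/(M/N), with S the hypergeometric upper tail (equivalently a
one-tailed Fisher's exact test), computed via `scipy.stats.hypergeom`'s
log-space survival function and validated in the test suite against
exhaustive enumeration of all draws for populations up to N = 15.
Degenerate inputs (n = 0 or M = 0) yield E = 0 and S = 1: a term with
no candidate overlap is simply not enrichable. N = 0 (an empty
component) is an error rather than a silent zero. The upper summation
limit is n, with C(a, b) = 0 whenever b > a, which equals the min(n, M)
form. Ranking ties break deterministically: descending E, ascending S,
descending m, then lexicographic term id — m as the first substantive
tie key matches the intent of squaring m (prefer the higher-degree term
among near-equals).

Each component has its own population: N is the number of filtered
proteins with ≥ 1 association in that component. Whether N should be
computed over the whole store or the taxon-filtered view is an open
choice; the filtered view is used so that scores are internally
consistent with the proteins that can actually enter the graph.

### Bioactivity selection

Records qualify if the target is a single protein of an active taxon,
the standard type is one of IC50/EC50/AC50/XC50/Ki/Kd/potency
(case-insensitive), and a pChEMBL value ≥ 5 is present (pChEMBL 5 ≡
10 µM; the unit conversion keeps the decimal exponent as an integer so
round concentrations convert exactly). The pool search starts at
pChEMBL 8 and moves in 0.5-unit steps (invented granularity; the
procedure is described without a step size), lowering while fewer than
1000 distinct compounds qualify — never below the floor of 5 — or
raising while more than 2500 do, with a 20-iteration guard. The
direction is fixed by the first run; because the count is monotone in
the cutoff, the scan lands in [1000, 2500] whenever any grid cutoff
achieves it, and otherwise accepts the terminal pool with an explicit
out-of-bounds flag. "1000–2500 compound entries" is read as distinct
compounds (not bioactivity rows); both bounds are parameters.

### Compound clustering

Clusters are computed once per datastore over all stored fingerprints
(leader algorithm: canonical processing order by descending on-bit
count then id; a compound joins the first representative within
Tanimoto ≥ 0.5, else founds a cluster) and cached, so cluster identity
is global — the experimental and predicted selection routes share it,
and a structural family admitted through one route blocks the other.
Leader clustering guarantees member–representative similarity ≥ 0.5
and representative–representative similarity < 0.5, but not full
within-cluster clique similarity; a single-linkage variant (connected
components of the ≥ 0.5 similarity graph) is available behind
`cluster_method="single_linkage"` for sensitivity checks. Fingerprints
are supplied precomputed (on-bit lists with a width) so the package
runs without a chemistry toolkit; any circular fingerprint of the
ECFP4 family fits the interface. Predicted entries that reference
drugs have no fingerprint and fall back to singleton clusters.

An optional significance gate for ligands (E > 1 and S < 0.05, the
setting used for curated infectious-disease graphs) is available but
off by default.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| k per component | 10 | node budget per biological component |
| taxa | {9606} | NCBI taxon filter for gene/protein entries |
| reviewed_only | true | exclude unreviewed protein entries |
| min_ppi_cross / min_ppi_within | 0 / 0 | PPI confidence floors (0.35/0.6 reproduces the host–pathogen setting) |
| pool bounds | 1000–2500 | distinct-compound window of the cutoff search |
| pool start / floor / step | 8 / 5 / 0.5 | pChEMBL cutoff trajectory |
| cluster threshold | 0.5 | Tanimoto cutoff of compound clustering |
| phenotype_thinning | false | reject a phenotype whose parent/child is already selected |

## Diversity and stability analyses

`node_identity` counts shared nodes (matched by id **and** component)
between two graphs; because the published identity percentages do not
pin down a denominator, the convention (jaccard/min/mean) is always
recorded in the output, with jaccard as default. `term_frequency_analysis`
compares a term's observed presence frequency g/G across G graphs with
its connectivity-expected frequency t·M_D/M_sum (clamped to 1 when the
budget exceeds the component's supply). Building a 2×2 table from an
expected *frequency* is under-determined; the implemented convention is
the pseudo-table [[g, G−g], [round(G·e), G−round(G·e)]] under a
one-tailed Fisher's exact test, with an exact binomial test
(g ~ Binomial(G, e)) behind a switch — the two agree on direction in
all tested settings.

## The synthetic generator

The generator emulates structure, not biology: identifiers are
synthetic and no real ontology is shipped. Proteins fall into a small
number of blocks; specific diseases/pathways/phenotypes annotate ~45%
of one block each, so terms of a block genuinely co-associate (the
property that makes related queries produce similar graphs); planted
hub terms annotate 80% of the whole store; PPIs are drawn mostly
within blocks; compounds include planted scaffold clusters whose
members share a seed fingerprint with a bit-replacement fraction
solved numerically so the expected member–member Tanimoto hits the
requested within-cluster similarity (default 0.7, against < 0.3
between clusters); pChEMBL values are uniform on [4, 10] by default so
both the activity floor and the cutoff search have bite. Default sizes
(200 proteins, 36 terms per component, 120 compounds) keep a full
200-graph diversity experiment under ~10 s on one CPU; the pool-bound
experiments use 5000 compounds. Per-component term counts exceed the
default node budget k in every block, as in any realistic store —
a component with fewer candidates than k would admit any term
regardless of ranking.

What passing tests on these fixtures do **not** show: robustness to
real ontology depth (the synthetic parent chains are shallow), to
heavy-tailed annotation distributions, or to the scale of real
compound libraries (millions of entries); identifier namespaces are
assumed disjoint across components.

## Numerical and design notes

- Duplicate PPI pairs collapse to the maximum confidence; self-loops
  are dropped at load. Unresolved cross-references drop the offending
  row (counted and logged) unless strict loading is requested.
- The same disease recorded by two sources remains two terms; real
  stores contain such near-duplicates and deduplication is a curation
  task, not a loader decision.
- Name resolution for queries: exact id, exact name, case-insensitive
  name; ambiguity is an error listing candidates.
- "is ortholog of" is part of the edge vocabulary (for imported curated
  graphs) but never emitted by the automatic pipeline.
- The 7-layer layout grouping is {core proteins, neighbour proteins,
  pathways, diseases, phenotypes, drugs, compounds}; 4-layer merges to
  {proteins, pathways, diseases+phenotypes, drugs+compounds}. Layouts
  emit coordinates only (evenly spaced angles per layer; nested layers
  share a centre with increasing radii, isolated layers get disjoint
  circles).

## Known limitations

- Leader clustering depends on the canonical processing order; a
  different order yields different (equally valid) representatives.
  Determinism is guaranteed, order-optimality is not.
- The edge-addition pass only considers ligands already selected as
  nodes; it never adds nodes.
- Enrichment treats core and neighbour proteins with equal weight; no
  confidence weighting of PPI-derived membership is applied.
- The frequency test's pseudo-table treats the expected count as if it
  were an observed cohort; the binomial switch exists precisely because
  this construction is a convention.
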