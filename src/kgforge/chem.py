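"""Bioactivity filtering, fingerprint similarity and compound clustering.

Small-molecule compounds enter a knowledge graph through their measured
(or predicted) activities against target proteins. The candidate pool is
assembled by an iterative pChEMBL-cutoff search: starting at pChEMBL 8,
the cutoff is lowered (never below 5, i.e. 10 uM) while fewer than 1000
distinct compounds qualify, or raised while more than 2500 do. Pooled
compounds are then clustered on fingerprint Tanimoto similarity at 0.5 so
that the final selection is structurally diverse: a compound whose cluster
is already represented in the graph is skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

#: Activity standard types that provide roughly comparable half-maximal
#: response measures; everything else is discarded.
ALLOWED_STANDARD_TYPES = frozenset(
    {"ic50", "ec50", "ac50", "xc50", "ki", "kd", "potency"}
)

#: decimal exponent of each unit relative to molar, kept as an integer so
#: round concentrations convert without floating-point drift
_UNIT_EXP10 = {
    "M": 0,
    "mM": -3,
    "µM": -6,
    "uM": -6,
    "nM": -9,
}


class ChemError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """A sparse binary substructure fingerprint (set of on-bit positions)."""

    on_bits: frozenset[int]
    width: int = 1024

    def __post_init__(self) -> None:
        object.__setattr__(self, "on_bits", frozenset(self.on_bits))
        if any(b < 0 or b >= self.width for b in self.on_bits):
            raise ChemError("fingerprint bit position outside width")

    def __len__(self) -> int:
        return len(self.on_bits)


@dataclass(frozen=True)
class BioactivityRecord:
    """One compound–target measurement on the pChEMBL scale."""

    compound_id: str
    target_protein_id: str
    standard_type: str
    pchembl: float | None
    target_kind: str = "single_protein"  # single_protein | complex | other
    taxon_id: int = 9606
    assay_class: str | None = None

    def __post_init__(self) -> None:
        if self.pchembl is not None and self.pchembl <= 0:
            raise ChemError(f"pchembl must be > 0, got {self.pchembl}")


@dataclass(frozen=True)
class PredictedDTI:
    compound_or_drug_id: str
    target_protein_id: str
    source_model: str
    score: float | None = None


@dataclass(frozen=True)
class CompoundPool:
    """Result of the iterative pChEMBL-cutoff pool assembly."""

    records: tuple[BioactivityRecord, ...]
    final_cutoff: float
    distinct_compounds: frozenset[str]
    iterations: int
    within_bounds: bool
    floor_relaxed: bool = False


@dataclass(frozen=True)
class ClusterAssignment:
    membership: Mapping[str, str]  # compound_id -> cluster_id
    representatives: Mapping[str, str]  # cluster_id -> representative compound

    def cluster_of(self, compound_id: str) -> str:
        return self.membership[compound_id]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pchembl_from_concentration(value: float, unit: str) -> float:
    """Negative log10 of a molar half-maximal concentration.

    ``pchembl_from_concentration(10, "µM") == 5``: a 10 uM XC50 sits exactly
    at the activity floor used for pool assembly.
    """
    if value <= 0:
        raise ChemError(f"concentration must be positive, got {value}")
    try:
        exponent = _UNIT_EXP10[unit]
    except KeyError:
        raise ChemError(f"unknown unit {unit!r}") from None
    return -(math.log10(value) + exponent)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|intersection| / |union| over on-bits; undefined for two empty sets."""
    if not a.on_bits and not b.on_bits:
        raise ChemError("Tanimoto undefined for two empty fingerprints")
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits | b.on_bits)
    return inter / union


def cluster_compounds(
    fingerprints: Mapping[str, Fingerprint],
    threshold: float = 0.5,
    method: str = "leader",
) -> ClusterAssignment:
    """Group compounds so cluster members are mutually similar at ``threshold``.

    The default is deterministic leader clustering: compounds are processed
    in canonical order (descending on-bit count, then id) and each joins
    the first existing representative within ``threshold`` Tanimoto, else
    founds a new cluster. Member-to-representative similarity >= threshold
    is the enforced contract; full within-cluster clique similarity is not
    guaranteed. ``method="single_linkage"`` instead takes connected
    components of the >=threshold similarity graph, for sensitivity checks.
    """
    if not 0 < threshold <= 1:
        raise ChemError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(fingerprints, key=lambda c: (-len(fingerprints[c]), c))
    if method == "leader":
        reps: list[str] = []
        membership: dict[str, str] = {}
        for cid in order:
            fp = fingerprints[cid]
            for rep in reps:
                if tanimoto(fp, fingerprints[rep]) >= threshold:
                    membership[cid] = rep
                    break
            else:
                reps.append(cid)
                membership[cid] = cid
        return ClusterAssignment(
            membership=membership, representatives={r: r for r in reps}
        )
    if method == "single_linkage":
        parent = {c: c for c in order}

        def find(c: str) -> str:
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for i, a in enumerate(order):
            for b in order[i + 1:]:
                if tanimoto(fingerprints[a], fingerprints[b]) >= threshold:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        membership = {c: find(c) for c in order}
        reps = sorted(set(membership.values()))
        return ClusterAssignment(
            membership=membership, representatives={r: r for r in reps}
        )
    raise ChemError(f"unknown clustering method {method!r}")


def filter_bioactivities(
    records: Iterable[BioactivityRecord],
    taxa: Iterable[int] = (9606,),
    allowed_standard_types: Iterable[str] | None = None,
    pchembl_min: float = 5.0,
) -> list[BioactivityRecord]:
    """Keep single-protein, taxon-matched, comparable-standard-type records
    with a recorded pChEMBL of at least ``pchembl_min``."""
    if pchembl_min < 0:
        raise ChemError("pchembl_min must be >= 0")
    taxa = frozenset(int(t) for t in taxa)
    allowed = (
        ALLOWED_STANDARD_TYPES
        if allowed_standard_types is None
        else frozenset(t.lower() for t in allowed_standard_types)
    )
    return [
        r
        for r in records
        if r.target_kind == "single_protein"
        and r.taxon_id in taxa
        and r.standard_type.lower() in allowed
        and r.pchembl is not None
        and r.pchembl >= pchembl_min
    ]


def assemble_compound_pool(
    records: Iterable[BioactivityRecord],
    target_proteins: Iterable[str],
    taxa: Iterable[int] = (9606,),
    lower: int = 1000,
    upper: int = 2500,
    start_cutoff: float = 8.0,
    floor: float = 5.0,
    step: float = 0.5,
    max_iter: int = 20,
) -> CompoundPool:
    """Iterative pChEMBL-cutoff search for a pool of 1000–2500 compounds.

    The first run at ``start_cutoff`` fixes the direction: too few distinct
    compounds -> lower the cutoff by ``step`` per iteration (never below
    ``floor``); too many -> raise it. The scan stops as soon as the count
    enters [lower, upper], or when the floor / ``max_iter`` is hit, in
    which case the pool is accepted as-is with ``within_bounds=False``.
    """
    if floor > start_cutoff:
        raise ChemError("floor must not exceed start_cutoff")
    if lower >= upper:
        raise ChemError("lower bound must be below upper bound")
    targets = frozenset(target_proteins)
    base = [
        r
        for r in filter_bioactivities(records, taxa=taxa, pchembl_min=floor)
        if r.target_protein_id in targets
    ]

    def pool_at(cutoff: float) -> list[BioactivityRecord]:
        return [r for r in base if r.pchembl >= cutoff]

    if not targets or not base:
        return CompoundPool(
            records=(),
            final_cutoff=start_cutoff,
            distinct_compounds=frozenset(),
            iterations=1,
            within_bounds=False,
        )

    cutoff = start_cutoff
    iterations = 1
    selected = pool_at(cutoff)
    count = len({r.compound_id for r in selected})
    direction = 0 if lower <= count <= upper else (-1 if count < lower else +1)
    floor_relaxed = False
    while not lower <= count <= upper and iterations < max_iter:
        if direction < 0:
            if cutoff <= floor:
                floor_relaxed = True
                break
            cutoff = max(floor, cutoff - step)
        else:
            cutoff = cutoff + step
        iterations += 1
        selected = pool_at(cutoff)
        count = len({r.compound_id for r in selected})
        # when raising, any count at or below the upper bound terminates
        if direction > 0 and count <= upper:
            break
    distinct = frozenset(r.compound_id for r in selected)
    return CompoundPool(
        records=tuple(
            sorted(selected, key=lambda r: (r.compound_id, r.target_protein_id,
                                            -(r.pchembl or 0.0)))
        ),
        final_cutoff=cutoff,
        distinct_compounds=distinct,
        iterations=iterations,
        within_bounds=lower <= len(distinct) <= upper,
        floor_relaxed=floor_relaxed,
    )


def select_diverse_compounds(
    ranked_compounds: Sequence[str],
    clusters: ClusterAssignment | Mapping[str, str],
    k: int,
    already_present_clusters: Iterable[str] = (),
) -> list[str]:
    """Walk an enrichment ranking keeping at most one compound per cluster.

    A compound whose structural cluster is already represented — in the
    growing graph or earlier in this selection — is discarded; the walk
    stops after ``k`` admissions.
    """
    membership = (
        clusters.membership if isinstance(clusters, ClusterAssignment) else clusters
    )
    seen = set(already_present_clusters)
    selected: list[str] = []
    for cid in ranked_compounds:
        if len(selected) >= k:
            break
        cluster = membership[cid]
        if cluster in seen:
            continue
        seen.add(cluster)
        selected.append(cid)
    return selected
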