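"""Synthetic datastore generation with controlled association structure.

The generator emulates the statistical structure a query-driven KG
builder has to cope with, not real biology: proteins fall into a few
association blocks (diseases, pathways and phenotypes of one block share
a protein neighbourhood, like disease families sharing mechanisms),
planted promiscuous hub terms annotate a large fraction of all proteins,
compounds carry planted structural scaffold clusters, and bioactivities
have a tunable pChEMBL distribution so both the activity floor and the
iterative cutoff search have bite. Every output is reproducible from the
seed, and ground truth (hubs, clusters, expected query cores) is written
alongside the collections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .chem import Fingerprint, BioactivityRecord, PredictedDTI
from .datastore import (
    CompoundRecord,
    Datastore,
    DrugRecord,
    PPIRecord,
    ProteinRecord,
    TermRecord,
    write_datastore,
)
from .kg_builder import QuerySpec

_STANDARD_TYPES = ("IC50", "EC50", "AC50", "XC50", "Ki", "Kd", "Potency")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults give a small desk-scale store."""

    n_proteins: int = 200
    taxa_mix: Mapping[int, float] = field(
        default_factory=lambda: {9606: 0.85, 10090: 0.15}
    )
    reviewed_frac: float = 0.9
    n_blocks: int = 3
    ppi_mean_degree: float = 4.0
    ppi_within_block_frac: float = 0.9
    # per-component specific (block-local) terms
    n_diseases: int = 36
    n_pathways: int = 36
    n_phenotypes: int = 36
    annotation_fraction: float = 0.45
    # planted promiscuous hubs, per component listed in hub_components
    n_hub_terms: int = 2
    hub_fraction: float = 0.8
    hub_components: tuple[str, ...] = ("disease", "pathway", "phenotype")
    # disease cross-component links
    links_per_disease: int = 2
    # drugs
    n_drugs: int = 15
    drug_targets_mean: float = 3.0
    drug_xref_frac: float = 0.4
    # compounds and planted scaffold clusters
    n_compounds: int = 120
    n_scaffold_clusters: int = 3
    cluster_size: int = 10
    within_sim: float = 0.7
    between_sim: float = 0.2
    fp_width: int = 1024
    fp_bits: int = 64
    # bioactivities
    n_bioactivities: int = 400
    n_bioactivity_targets: int | None = None
    pchembl_range: tuple[float, float] = (4.0, 10.0)
    frac_bad_standard_type: float = 0.0
    frac_missing_pchembl: float = 0.0
    frac_nonsingle_target: float = 0.0
    # predictions
    n_predicted: int = 100
    pred_drug_frac: float = 0.2
    # optional plant for single-gene builds: one gene annotated to this
    # many dedicated disease terms of varying connectivity
    planted_gene_diseases: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_proteins, self.n_diseases, self.n_pathways, self.n_phenotypes,
            self.n_drugs, self.n_compounds, self.n_bioactivities, self.n_predicted,
        ) < 0:
            raise SynthError("all counts must be >= 0")
        if not 0.0 <= self.between_sim < self.within_sim <= 1.0:
            raise SynthError("need 0 <= between_sim < within_sim <= 1")
        if self.n_hub_terms > min(self.n_diseases, self.n_pathways,
                                  self.n_phenotypes) and self.hub_components:
            raise SynthError("hub count exceeds term count")
        if self.n_scaffold_clusters * self.cluster_size > self.n_compounds:
            raise SynthError("scaffold clusters exceed compound count")


def _flip_fraction(within_sim: float) -> float:
    """Per-member fraction of seed bits replaced so that the expected
    member–member Tanimoto hits the requested within-cluster similarity.

    Two members independently keep a (1-f) fraction of the b seed bits
    and replace the rest with fresh random bits (collisions negligible at
    b << width), so E[T] ~ (1-f)^2 / (2 - (1-f)^2).
    """
    def gap(f: float) -> float:
        s = (1.0 - f) ** 2
        return s / (2.0 - s) - within_sim

    if gap(0.0) <= 0:
        return 0.0
    return float(brentq(gap, 0.0, 1.0, xtol=1e-12))


def _scaffold_fingerprints(
    params: SynthParams, rng: np.random.Generator
) -> tuple[dict[str, Fingerprint], dict[str, list[str]]]:
    """Planted clusters first, then unstructured singleton compounds."""
    fingerprints: dict[str, Fingerprint] = {}
    clusters: dict[str, list[str]] = {}
    f = _flip_fraction(params.within_sim)
    n_flip = int(round(f * params.fp_bits))
    idx = 0
    for c in range(params.n_scaffold_clusters):
        seed_bits = rng.choice(params.fp_width, size=params.fp_bits, replace=False)
        members = []
        for _ in range(params.cluster_size):
            cid = f"C{idx:05d}"
            idx += 1
            keep = rng.choice(params.fp_bits, size=params.fp_bits - n_flip,
                              replace=False)
            bits = set(int(b) for b in seed_bits[keep])
            candidates = [b for b in range(params.fp_width) if b not in set(map(int, seed_bits))]
            fresh = rng.choice(len(candidates), size=n_flip, replace=False)
            bits.update(candidates[i] for i in fresh)
            fingerprints[cid] = Fingerprint(on_bits=frozenset(bits),
                                            width=params.fp_width)
            members.append(cid)
        clusters[f"scaffold{c}"] = members
    while idx < params.n_compounds:
        cid = f"C{idx:05d}"
        idx += 1
        bits = rng.choice(params.fp_width, size=params.fp_bits, replace=False)
        fingerprints[cid] = Fingerprint(
            on_bits=frozenset(int(b) for b in bits), width=params.fp_width
        )
    return fingerprints, clusters


def generate_datastore(
    params: SynthParams, out_dir: str | Path | None = None
) -> tuple[Datastore, dict]:
    """Build a fully indexed synthetic Datastore plus its ground truth.

    When ``out_dir`` is given, all seven collection TSVs, manifest.json
    and ground_truth.json are written there (byte-identical across runs
    with the same params).
    """
    rng = np.random.default_rng(params.rng_seed)

    # ---------------------------------------------------------- proteins
    taxa = sorted(params.taxa_mix)
    probs = np.array([params.taxa_mix[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    taxon_draw = rng.choice(len(taxa), size=params.n_proteins, p=probs)
    reviewed_draw = rng.random(params.n_proteins) < params.reviewed_frac
    protein_ids = [f"P{i:04d}" for i in range(params.n_proteins)]
    protein_taxon = {
        pid: taxa[taxon_draw[i]] for i, pid in enumerate(protein_ids)
    }
    protein_reviewed = {
        pid: bool(reviewed_draw[i]) for i, pid in enumerate(protein_ids)
    }
    blocks: list[list[str]] = [
        [pid for i, pid in enumerate(protein_ids) if i % params.n_blocks == b]
        for b in range(params.n_blocks)
    ]

    # ------------------------------------------------------------- terms
    def block_members(block: Sequence[str], fraction: float) -> list[str]:
        size = max(1, int(round(fraction * len(block))))
        picked = rng.choice(len(block), size=min(size, len(block)), replace=False)
        return sorted(block[i] for i in picked)

    term_members: dict[tuple[str, str], list[str]] = {}
    term_block: dict[str, int] = {}
    hubs: dict[str, list[str]] = {c: [] for c in ("disease", "pathway", "phenotype")}
    specific: dict[str, list[str]] = {c: [] for c in ("disease", "pathway", "phenotype")}
    for component, prefix, count in (
        ("disease", "D", params.n_diseases),
        ("pathway", "PW", params.n_pathways),
        ("phenotype", "HP", params.n_phenotypes),
    ):
        n_hubs = params.n_hub_terms if component in params.hub_components else 0
        for i in range(count):
            if i < n_hubs:
                term_id = f"{prefix}HUB{i:02d}"
                members = block_members(protein_ids, params.hub_fraction)
                hubs[component].append(term_id)
            else:
                term_id = f"{prefix}{i:04d}"
                block_idx = i % params.n_blocks
                members = block_members(blocks[block_idx], params.annotation_fraction)
                specific[component].append(term_id)
                term_block[term_id] = block_idx
            term_members[(term_id, component)] = members

    planted_gene = None
    planted_diseases: list[str] = []
    if params.planted_gene_diseases > 0:
        planted_gene = protein_ids[0]
        protein_taxon[planted_gene] = 9606
        protein_reviewed[planted_gene] = True
        for i in range(params.planted_gene_diseases):
            term_id = f"DPL{i:04d}"
            extra = int(rng.integers(0, max(2, params.n_proteins // 10)))
            others = rng.choice(params.n_proteins, size=extra, replace=False)
            members = sorted({planted_gene} | {protein_ids[j] for j in others})
            term_members[(term_id, "disease")] = members
            planted_diseases.append(term_id)

    # disease cross-component links for drug/disease/pathway edge closure
    terms: dict[tuple[str, str], TermRecord] = {}
    pathway_by_block: dict[int, list[str]] = {}
    phenotype_by_block: dict[int, list[str]] = {}
    for t in specific["pathway"]:
        pathway_by_block.setdefault(term_block[t], []).append(t)
    for t in specific["phenotype"]:
        phenotype_by_block.setdefault(term_block[t], []).append(t)
    prev_phenotype: str | None = None
    for (term_id, component) in sorted(term_members):
        pathway_ids: tuple[str, ...] = ()
        phenotype_ids: tuple[str, ...] = ()
        parent_ids: tuple[str, ...] = ()
        if component == "disease" and term_id in term_block:
            block = term_block[term_id]
            pool_pw = pathway_by_block.get(block, [])
            pool_ph = phenotype_by_block.get(block, [])
            k = params.links_per_disease
            if pool_pw:
                picked = rng.choice(len(pool_pw), size=min(k, len(pool_pw)),
                                    replace=False)
                pathway_ids = tuple(sorted(pool_pw[i] for i in picked))
            if pool_ph:
                picked = rng.choice(len(pool_ph), size=min(k, len(pool_ph)),
                                    replace=False)
                phenotype_ids = tuple(sorted(pool_ph[i] for i in picked))
        if component == "phenotype":
            # shallow parent chains for ontology thinning
            if prev_phenotype is not None and int(term_id[-1], 36) % 2 == 1:
                parent_ids = (prev_phenotype,)
            prev_phenotype = term_id
        terms[(term_id, component)] = TermRecord(
            term_id=term_id,
            component=component,
            name=f"{component} {term_id}",
            source="synthetic",
            parent_ids=parent_ids,
            pathway_ids=pathway_ids,
            phenotype_ids=phenotype_ids,
        )

    # invert term membership onto protein annotation columns
    annot: dict[str, dict[str, list[str]]] = {
        pid: {"disease": [], "pathway": [], "phenotype": []}
        for pid in protein_ids
    }
    for (term_id, component), members in sorted(term_members.items()):
        for pid in members:
            annot[pid][component].append(term_id)
    proteins = {
        pid: ProteinRecord(
            protein_id=pid,
            gene_symbol=f"G{pid[1:]}",
            taxon_id=protein_taxon[pid],
            reviewed=protein_reviewed[pid],
            disease_ids=tuple(sorted(annot[pid]["disease"])),
            pathway_ids=tuple(sorted(annot[pid]["pathway"])),
            phenotype_ids=tuple(sorted(annot[pid]["phenotype"])),
        )
        for pid in protein_ids
    }

    # -------------------------------------------------------------- PPIs
    n_edges = int(round(params.n_proteins * params.ppi_mean_degree / 2))
    seen_pairs: set[tuple[str, str]] = set()
    ppis: list[PPIRecord] = []
    attempts = 0
    while len(ppis) < n_edges and attempts < 20 * n_edges:
        attempts += 1
        a_idx = int(rng.integers(params.n_proteins))
        a = protein_ids[a_idx]
        if rng.random() < params.ppi_within_block_frac:
            block = blocks[a_idx % params.n_blocks]
            b = block[int(rng.integers(len(block)))]
        else:
            b = protein_ids[int(rng.integers(params.n_proteins))]
        if a == b:
            continue
        pair = tuple(sorted((a, b)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        conf = float(np.round(0.2 + 0.8 * rng.random(), 4))
        ppis.append(PPIRecord(pair[0], pair[1], conf))
    ppis.sort(key=lambda r: r.pair)

    # --------------------------------------------------------- compounds
    fingerprints, scaffold_clusters = _scaffold_fingerprints(params, rng)
    compounds = {
        cid: CompoundRecord(compound_id=cid, fingerprint=fp,
                            name=f"compound {cid}")
        for cid, fp in sorted(fingerprints.items())
    }
    compound_ids = sorted(compounds)

    # ------------------------------------------------------------- drugs
    human_reviewed = [
        pid for pid in protein_ids
        if protein_taxon[pid] == 9606 and protein_reviewed[pid]
    ]
    disease_ids_all = sorted(t for (t, c) in term_members if c == "disease")
    drugs: dict[str, DrugRecord] = {}
    xref_draw = rng.random(params.n_drugs) < params.drug_xref_frac
    for i in range(params.n_drugs):
        drug_id = f"DR{i:04d}"
        n_targets = max(1, int(rng.poisson(params.drug_targets_mean)))
        picked = rng.choice(len(human_reviewed),
                            size=min(n_targets, len(human_reviewed)),
                            replace=False)
        targets = tuple(sorted(human_reviewed[j] for j in picked))
        n_ind = int(rng.integers(1, 3))
        picked = rng.choice(len(disease_ids_all),
                            size=min(n_ind, len(disease_ids_all)), replace=False)
        indications = tuple(sorted(disease_ids_all[j] for j in picked))
        xref = None
        if xref_draw[i] and compound_ids:
            xref = compound_ids[int(rng.integers(len(compound_ids)))]
        drugs[drug_id] = DrugRecord(
            drug_id=drug_id,
            name=f"drug {drug_id}",
            status="approved" if rng.random() < 0.7 else "investigational",
            target_protein_ids=targets,
            indication_disease_ids=indications,
            compound_xref=xref,
        )

    # ------------------------------------------------------ bioactivities
    if params.n_bioactivity_targets is not None:
        target_pool = human_reviewed[: params.n_bioactivity_targets]
    else:
        target_pool = human_reviewed
    lo, hi = params.pchembl_range
    bioactivities: list[BioactivityRecord] = []
    for _ in range(params.n_bioactivities):
        cid = compound_ids[int(rng.integers(len(compound_ids)))]
        pid = target_pool[int(rng.integers(len(target_pool)))]
        r = rng.random()
        standard_type = (
            "GI50" if r < params.frac_bad_standard_type
            else _STANDARD_TYPES[int(rng.integers(len(_STANDARD_TYPES)))]
        )
        pchembl: float | None = float(np.round(lo + (hi - lo) * rng.random(), 3))
        if rng.random() < params.frac_missing_pchembl:
            pchembl = None
        target_kind = (
            "complex" if rng.random() < params.frac_nonsingle_target
            else "single_protein"
        )
        bioactivities.append(
            BioactivityRecord(
                compound_id=cid,
                target_protein_id=pid,
                standard_type=standard_type,
                pchembl=pchembl,
                target_kind=target_kind,
                taxon_id=protein_taxon[pid],
            )
        )

    # -------------------------------------------------------- predictions
    drug_ids = sorted(drugs)
    predicted: list[PredictedDTI] = []
    for _ in range(params.n_predicted):
        if drug_ids and rng.random() < params.pred_drug_frac:
            ligand = drug_ids[int(rng.integers(len(drug_ids)))]
        else:
            ligand = compound_ids[int(rng.integers(len(compound_ids)))]
        pid = target_pool[int(rng.integers(len(target_pool)))]
        predicted.append(
            PredictedDTI(
                compound_or_drug_id=ligand,
                target_protein_id=pid,
                source_model="deepscreen" if rng.random() < 0.5 else "mdeepred",
                score=float(np.round(rng.random(), 3)),
            )
        )

    datastore = Datastore(
        proteins=proteins,
        ppis=ppis,
        terms=terms,
        drugs=drugs,
        compounds=compounds,
        bioactivities=bioactivities,
        predicted_dtis=predicted,
    )
    ground_truth = {
        "params": {
            k: (dict(v) if isinstance(v, Mapping) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
        "blocks": [sorted(b) for b in blocks],
        "hub_terms": hubs,
        "specific_terms": specific,
        "scaffold_clusters": scaffold_clusters,
        "planted_gene": planted_gene,
        "planted_gene_diseases": planted_diseases,
        "query_expected_core": {
            term_id: members
            for (term_id, component), members in sorted(term_members.items())
            if component == "disease"
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        write_datastore(datastore, out)
        (out / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1, sort_keys=True)
        )
    return datastore, ground_truth


def generate_query_set(
    datastore: Datastore,
    n_per_component: int = 2,
    combinatory: int = 1,
    seed: int = 0,
    components: Sequence[str] = ("protein", "disease", "pathway", "phenotype",
                                 "drug", "compound"),
    exclude: Mapping[str, Sequence[str]] | None = None,
) -> list[QuerySpec]:
    """Uniformly sampled single-term queries per component plus
    combinatory queries of one term per component."""
    rng = np.random.default_rng(seed)
    exclude = exclude or {}

    def candidates(component: str) -> list[str]:
        if component == "protein":
            ids = sorted(datastore.proteins)
        elif component in ("disease", "pathway", "phenotype"):
            ids = sorted(t for (t, c) in datastore.terms if c == component)
        elif component == "drug":
            ids = sorted(datastore.drugs)
        elif component == "compound":
            ids = sorted(datastore.compounds)
        else:
            raise SynthError(f"unknown component {component!r}")
        banned = set(exclude.get(component, ()))
        return [i for i in ids if i not in banned]

    queries: list[QuerySpec] = []
    pools = {c: candidates(c) for c in components}
    for component in components:
        pool = pools[component]
        if not pool:
            continue
        picked = rng.choice(len(pool), size=min(n_per_component, len(pool)),
                            replace=False)
        for i in sorted(int(j) for j in picked):
            queries.append(QuerySpec(terms=((component, pool[i]),)))
    for _ in range(combinatory):
        terms = tuple(
            (c, pools[c][int(rng.integers(len(pools[c])))])
            for c in components
            if pools[c]
        )
        if terms:
            queries.append(QuerySpec(terms=terms))
    return queries
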