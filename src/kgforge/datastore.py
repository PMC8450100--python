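"""Flat-file collection store for heterogeneous biomedical entities.

The store holds seven tables — proteins, protein–protein interactions
(PPIs), ontology-like terms (diseases, pathways, phenotypes), drugs,
small-molecule compounds, experimental bioactivities and predicted
drug–target interactions — together with the per-component annotation
indices (term id -> associated protein ids) that every enrichment-based
filtering step consumes.

Genes and proteins are a single merged entity keyed by protein accession.
Collections live on disk as one UTF-8 TSV per table plus a JSON manifest;
multi-valued cells are pipe-delimited.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .chem import BioactivityRecord, Fingerprint, PredictedDTI

logger = logging.getLogger(__name__)

#: The six biological components whose terms can enter a knowledge graph.
ANNOTATION_COMPONENTS = (
    "disease",
    "pathway",
    "phenotype",
    "drug",
    "compound-experimental",
    "compound-predicted",
)

TERM_COMPONENTS = ("disease", "pathway", "phenotype")

COLLECTIONS = (
    "proteins",
    "ppis",
    "terms",
    "drugs",
    "compounds",
    "bioactivities",
    "predicted_dtis",
)


class DatastoreError(ValueError):
    """Raised for malformed collections or unresolved cross-references."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_symbol: str
    taxon_id: int
    reviewed: bool
    disease_ids: tuple[str, ...] = ()
    pathway_ids: tuple[str, ...] = ()
    phenotype_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise DatastoreError("protein_id must be non-empty")
        if self.taxon_id <= 0:
            raise DatastoreError(f"taxon_id must be > 0 ({self.protein_id})")

    def term_ids(self, component: str) -> tuple[str, ...]:
        if component == "disease":
            return self.disease_ids
        if component == "pathway":
            return self.pathway_ids
        if component == "phenotype":
            return self.phenotype_ids
        raise DatastoreError(f"unknown annotation component: {component!r}")


@dataclass(frozen=True)
class PPIRecord:
    """An undirected protein–protein interaction with a source confidence."""

    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise DatastoreError(
                f"PPI confidence out of [0,1]: {self.confidence}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.protein_a, self.protein_b))
        return a, b


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    component: str
    name: str
    source: str = ""
    parent_ids: tuple[str, ...] = ()
    # Cross-component relations recorded on disease terms: the pathways a
    # disease modulates and the phenotypes it is associated with.
    pathway_ids: tuple[str, ...] = ()
    phenotype_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.component not in TERM_COMPONENTS:
            raise DatastoreError(
                f"invalid term component {self.component!r} for {self.term_id}"
            )


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    status: str  # approved | investigational
    target_protein_ids: tuple[str, ...] = ()
    indication_disease_ids: tuple[str, ...] = ()
    compound_xref: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("approved", "investigational"):
            raise DatastoreError(
                f"invalid drug status {self.status!r} for {self.drug_id}"
            )


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    fingerprint: Fingerprint
    name: str = ""


def _split(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(p for p in text.split("|") if p)


def _join(values: Iterable[str]) -> str:
    return "|".join(values)


@dataclass
class Datastore:
    """In-memory view of all collections plus derived association indices.

    Instances are cheap views: the filter methods return new Datastores
    sharing record objects but with all indices recomputed.
    """

    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    ppis: list[PPIRecord] = field(default_factory=list)
    terms: dict[tuple[str, str], TermRecord] = field(default_factory=dict)
    drugs: dict[str, DrugRecord] = field(default_factory=dict)
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    bioactivities: list[BioactivityRecord] = field(default_factory=list)
    predicted_dtis: list[PredictedDTI] = field(default_factory=list)
    warnings: Counter = field(default_factory=Counter)

    # derived
    annotation_index: dict[str, dict[str, frozenset[str]]] = field(
        default_factory=dict, repr=False
    )
    ppi_index: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    component_totals: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._cluster_cache: dict = {}
        self.reindex()

    def compound_clusters(self, threshold: float = 0.5,
                          method: str = "leader"):
        """Structural cluster assignment over all stored compounds.

        Computed once per store (cluster identity is global, shared by
        every graph built from it) and cached; views inherit the cache
        because they share the compound table.
        """
        from .chem import cluster_compounds

        key = (threshold, method)
        if key not in self._cluster_cache:
            fps = {
                cid: rec.fingerprint
                for cid, rec in self.compounds.items()
                if rec.fingerprint.on_bits
            }
            self._cluster_cache[key] = cluster_compounds(
                fps, threshold=threshold, method=method
            )
        return self._cluster_cache[key]

    # ------------------------------------------------------------------ index
    def reindex(self) -> None:
        self.annotation_index = {
            c: build_annotation_index(self, c) for c in ANNOTATION_COMPONENTS
        }
        ppi_index: dict[str, set[str]] = {}
        for rec in self.ppis:
            ppi_index.setdefault(rec.protein_a, set()).add(rec.protein_b)
            ppi_index.setdefault(rec.protein_b, set()).add(rec.protein_a)
        self.ppi_index = {p: frozenset(v) for p, v in ppi_index.items()}
        self.component_totals = {
            c: len(
                {p for members in self.annotation_index[c].values() for p in members}
            )
            for c in ANNOTATION_COMPONENTS
        }
        # proteins with at least one PPI: the population for neighbour scoring
        self.component_totals["ppi"] = len(self.ppi_index)

    def term(self, term_id: str, component: str) -> TermRecord | None:
        return self.terms.get((term_id, component))

    def terms_of(self, component: str) -> list[TermRecord]:
        return sorted(
            (t for t in self.terms.values() if t.component == component),
            key=lambda t: t.term_id,
        )

    # --------------------------------------------------------------- filters
    def filter_proteins_by_taxon(
        self,
        taxa: Iterable[int],
        reviewed_only: bool = True,
        allow_unreviewed: Iterable[str] = (),
    ) -> "Datastore":
        """Restrict the view to proteins of the given taxa.

        Unreviewed entries are excluded when ``reviewed_only`` unless
        explicitly allow-listed by accession.
        """
        taxa = frozenset(int(t) for t in taxa)
        if not taxa:
            raise DatastoreError("taxa must be non-empty")
        allow = frozenset(allow_unreviewed)
        kept = {
            pid: rec
            for pid, rec in self.proteins.items()
            if rec.taxon_id in taxa
            and (rec.reviewed or not reviewed_only or pid in allow)
        }
        if not kept:
            logger.warning("taxon filter %s left zero proteins", sorted(taxa))
        return self._view(kept, self.ppis)

    def filter_ppis_by_confidence(
        self,
        min_cross: float,
        min_within: float,
        cross_predicate: Callable[[ProteinRecord, ProteinRecord], bool] | None = None,
    ) -> "Datastore":
        """Drop PPI edges below a confidence threshold.

        Cross-category pairs (by default: different taxa, e.g. host–virus)
        use ``min_cross``; within-category pairs use ``min_within``.
        """
        if cross_predicate is None:
            cross_predicate = lambda a, b: a.taxon_id != b.taxon_id  # noqa: E731
        kept_ppis = []
        for rec in self.ppis:
            pa = self.proteins.get(rec.protein_a)
            pb = self.proteins.get(rec.protein_b)
            if pa is None or pb is None:
                continue
            threshold = min_cross if cross_predicate(pa, pb) else min_within
            if rec.confidence >= threshold:
                kept_ppis.append(rec)
        return self._view(dict(self.proteins), kept_ppis)

    def _view(
        self, proteins: dict[str, ProteinRecord], ppis: Sequence[PPIRecord]
    ) -> "Datastore":
        visible = set(proteins)
        ppis = [
            r for r in ppis if r.protein_a in visible and r.protein_b in visible
        ]
        view = Datastore(
            proteins=proteins,
            ppis=list(ppis),
            terms=dict(self.terms),
            drugs=dict(self.drugs),
            compounds=dict(self.compounds),
            bioactivities=list(self.bioactivities),
            predicted_dtis=list(self.predicted_dtis),
            warnings=Counter(self.warnings),
        )
        view._cluster_cache = self._cluster_cache  # compounds are shared
        return view


def build_annotation_index(
    datastore: Datastore, component: str
) -> dict[str, frozenset[str]]:
    """term_id -> visible proteins associated with it, for one component.

    Drug associations come from drug target lists, experimental-compound
    associations from single-protein bioactivities, predicted-compound
    associations from the predicted DTI table; the three term components
    come from the protein annotation columns.
    """
    visible = set(datastore.proteins)
    raw: dict[str, set[str]] = {}
    if component in TERM_COMPONENTS:
        for pid, rec in datastore.proteins.items():
            for term_id in rec.term_ids(component):
                raw.setdefault(term_id, set()).add(pid)
    elif component == "drug":
        for drug in datastore.drugs.values():
            members = {t for t in drug.target_protein_ids if t in visible}
            if members:
                raw[drug.drug_id] = members
    elif component == "compound-experimental":
        for rec in datastore.bioactivities:
            if rec.target_kind != "single_protein":
                continue
            if rec.target_protein_id in visible:
                raw.setdefault(rec.compound_id, set()).add(rec.target_protein_id)
    elif component == "compound-predicted":
        for rec in datastore.predicted_dtis:
            if rec.target_protein_id in visible:
                raw.setdefault(rec.compound_or_drug_id, set()).add(
                    rec.target_protein_id
                )
    else:
        raise DatastoreError(f"unknown component: {component!r}")
    return {t: frozenset(m) for t, m in raw.items() if m}


# ---------------------------------------------------------------------- load
def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatastoreError(f"{name}: missing columns {missing}")


def _read_tsv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise DatastoreError(f"missing collection file: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def load_datastore(manifest: str | Path | Mapping[str, str], strict: bool = False) -> Datastore:
    """Load and index all collections named by a manifest.

    The manifest is a JSON file (or mapping) of collection name -> path,
    relative paths resolved against the manifest's directory. In strict
    mode any unresolved cross-reference raises; otherwise offending rows
    (or individual references) are dropped and counted in
    ``Datastore.warnings``.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        mapping = json.loads(manifest_path.read_text())
        base = manifest_path.parent
    else:
        mapping = dict(manifest)
        base = Path(".")
    missing = [c for c in COLLECTIONS if c not in mapping]
    if missing:
        raise DatastoreError(f"manifest missing collections: {missing}")
    paths = {c: (base / mapping[c]) for c in COLLECTIONS}
    warnings: Counter = Counter()

    def problem(key: str, message: str) -> None:
        if strict:
            raise DatastoreError(message)
        warnings[key] += 1
        logger.warning(message)

    # terms first so protein annotations can be cross-checked
    terms: dict[tuple[str, str], TermRecord] = {}
    df = _read_tsv(paths["terms"], "terms")
    if len(df):
        _require_columns(df, ["term_id", "component", "name"], "terms.tsv")
        for row in df.itertuples(index=False):
            rec = TermRecord(
                term_id=row.term_id,
                component=row.component,
                name=row.name,
                source=getattr(row, "source", ""),
                parent_ids=_split(getattr(row, "parent_ids", "")),
                pathway_ids=_split(getattr(row, "pathway_ids", "")),
                phenotype_ids=_split(getattr(row, "phenotype_ids", "")),
            )
            key = (rec.term_id, rec.component)
            if key in terms:
                raise DatastoreError(f"duplicate term: {key}")
            terms[key] = rec
    term_ids = {c: {t for (t, comp) in terms if comp == c} for c in TERM_COMPONENTS}

    proteins: dict[str, ProteinRecord] = {}
    df = _read_tsv(paths["proteins"], "proteins")
    if len(df):
        _require_columns(
            df, ["protein_id", "gene_symbol", "taxon_id", "reviewed"], "proteins.tsv"
        )
        for row in df.itertuples(index=False):
            if row.protein_id in proteins:
                raise DatastoreError(f"duplicate protein_id: {row.protein_id}")
            annots = {}
            for comp, col in (
                ("disease", "disease_ids"),
                ("pathway", "pathway_ids"),
                ("phenotype", "phenotype_ids"),
            ):
                ids = _split(getattr(row, col, ""))
                unknown = [t for t in ids if t not in term_ids[comp]]
                if unknown:
                    problem(
                        f"unresolved_{comp}_annotation",
                        f"protein {row.protein_id}: unknown {comp} terms {unknown}",
                    )
                    ids = tuple(t for t in ids if t in term_ids[comp])
                annots[col] = ids
            proteins[row.protein_id] = ProteinRecord(
                protein_id=row.protein_id,
                gene_symbol=row.gene_symbol,
                taxon_id=int(row.taxon_id),
                reviewed=str(row.reviewed).strip().lower() in ("1", "true", "yes"),
                **annots,
            )

    ppis: list[PPIRecord] = []
    best: dict[tuple[str, str], PPIRecord] = {}
    df = _read_tsv(paths["ppis"], "ppis")
    if len(df):
        _require_columns(df, ["protein_a", "protein_b", "confidence"], "ppis.tsv")
        for row in df.itertuples(index=False):
            if row.protein_a == row.protein_b:
                problem("ppi_self_loop", f"self-loop PPI dropped: {row.protein_a}")
                continue
            if row.protein_a not in proteins or row.protein_b not in proteins:
                problem(
                    "unresolved_ppi",
                    f"PPI references unknown protein: {row.protein_a}-{row.protein_b}",
                )
                continue
            rec = PPIRecord(row.protein_a, row.protein_b, float(row.confidence))
            prev = best.get(rec.pair)
            if prev is not None:
                # duplicates keep the maximum confidence (preserves evidence)
                problem("ppi_duplicate", f"duplicate PPI pair {rec.pair}")
                if rec.confidence > prev.confidence:
                    best[rec.pair] = rec
            else:
                best[rec.pair] = rec
        ppis = [best[p] for p in sorted(best)]

    compounds: dict[str, CompoundRecord] = {}
    df = _read_tsv(paths["compounds"], "compounds")
    if len(df):
        _require_columns(df, ["compound_id", "fingerprint", "fp_width"], "compounds.tsv")
        for row in df.itertuples(index=False):
            if row.compound_id in compounds:
                raise DatastoreError(f"duplicate compound_id: {row.compound_id}")
            bits = frozenset(
                int(b) for b in str(row.fingerprint).split(",") if b.strip()
            )
            compounds[row.compound_id] = CompoundRecord(
                compound_id=row.compound_id,
                fingerprint=Fingerprint(on_bits=bits, width=int(row.fp_width)),
                name=getattr(row, "name", ""),
            )

    drugs: dict[str, DrugRecord] = {}
    df = _read_tsv(paths["drugs"], "drugs")
    if len(df):
        _require_columns(df, ["drug_id", "name", "status"], "drugs.tsv")
        for row in df.itertuples(index=False):
            if row.drug_id in drugs:
                raise DatastoreError(f"duplicate drug_id: {row.drug_id}")
            targets = _split(getattr(row, "target_protein_ids", ""))
            unknown = [t for t in targets if t not in proteins]
            if unknown:
                problem(
                    "unresolved_drug_target",
                    f"drug {row.drug_id}: unknown targets {unknown}",
                )
                targets = tuple(t for t in targets if t in proteins)
            indications = _split(getattr(row, "indication_disease_ids", ""))
            unknown = [t for t in indications if t not in term_ids["disease"]]
            if unknown:
                problem(
                    "unresolved_drug_indication",
                    f"drug {row.drug_id}: unknown indications {unknown}",
                )
                indications = tuple(t for t in indications if t in term_ids["disease"])
            xref = str(getattr(row, "compound_xref", "")).strip() or None
            if xref is not None and xref not in compounds:
                problem(
                    "unresolved_compound_xref",
                    f"drug {row.drug_id}: unknown compound xref {xref}",
                )
                xref = None
            drugs[row.drug_id] = DrugRecord(
                drug_id=row.drug_id,
                name=row.name,
                status=row.status,
                target_protein_ids=targets,
                indication_disease_ids=indications,
                compound_xref=xref,
            )

    bioactivities: list[BioactivityRecord] = []
    df = _read_tsv(paths["bioactivities"], "bioactivities")
    if len(df):
        _require_columns(
            df,
            ["compound_id", "target_protein_id", "standard_type", "pchembl",
             "target_kind", "taxon_id"],
            "bioactivities.tsv",
        )
        for row in df.itertuples(index=False):
            if row.compound_id not in compounds:
                problem(
                    "unresolved_bioactivity_compound",
                    f"bioactivity references unknown compound {row.compound_id}",
                )
                continue
            if row.target_protein_id not in proteins:
                problem(
                    "unresolved_bioactivity_target",
                    f"bioactivity references unknown protein {row.target_protein_id}",
                )
                continue
            pchembl = str(row.pchembl).strip()
            bioactivities.append(
                BioactivityRecord(
                    compound_id=row.compound_id,
                    target_protein_id=row.target_protein_id,
                    standard_type=row.standard_type,
                    pchembl=float(pchembl) if pchembl else None,
                    target_kind=row.target_kind,
                    taxon_id=int(row.taxon_id),
                    assay_class=str(getattr(row, "assay_class", "")) or None,
                )
            )

    predicted: list[PredictedDTI] = []
    df = _read_tsv(paths["predicted_dtis"], "predicted_dtis")
    if len(df):
        _require_columns(
            df,
            ["compound_or_drug_id", "target_protein_id", "source_model"],
            "predicted_dtis.tsv",
        )
        for row in df.itertuples(index=False):
            cid = row.compound_or_drug_id
            if cid not in compounds and cid not in drugs:
                problem(
                    "unresolved_prediction_ligand",
                    f"predicted DTI references unknown ligand {cid}",
                )
                continue
            if row.target_protein_id not in proteins:
                problem(
                    "unresolved_prediction_target",
                    f"predicted DTI references unknown protein {row.target_protein_id}",
                )
                continue
            score = str(getattr(row, "score", "")).strip()
            predicted.append(
                PredictedDTI(
                    compound_or_drug_id=cid,
                    target_protein_id=row.target_protein_id,
                    source_model=row.source_model,
                    score=float(score) if score else None,
                )
            )

    return Datastore(
        proteins=proteins,
        ppis=ppis,
        terms=terms,
        drugs=drugs,
        compounds=compounds,
        bioactivities=bioactivities,
        predicted_dtis=predicted,
        warnings=warnings,
    )


# --------------------------------------------------------------------- write
def write_datastore(datastore: Datastore, out_dir: str | Path) -> Path:
    """Write all collections as TSVs plus a manifest.json; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = datastore_tables(datastore)
    manifest = {}
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(out / fname, sep="\t", index=False)
        manifest[name] = fname
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def datastore_tables(datastore: Datastore) -> dict[str, pd.DataFrame]:
    """The seven collections as DataFrames in canonical row/column order."""
    proteins = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "gene_symbol": r.gene_symbol,
                "taxon_id": r.taxon_id,
                "reviewed": str(r.reviewed).lower(),
                "disease_ids": _join(r.disease_ids),
                "pathway_ids": _join(r.pathway_ids),
                "phenotype_ids": _join(r.phenotype_ids),
            }
            for r in sorted(datastore.proteins.values(), key=lambda r: r.protein_id)
        ],
        columns=["protein_id", "gene_symbol", "taxon_id", "reviewed",
                 "disease_ids", "pathway_ids", "phenotype_ids"],
    )
    ppis = pd.DataFrame(
        [
            {"protein_a": r.protein_a, "protein_b": r.protein_b,
             "confidence": r.confidence}
            for r in sorted(datastore.ppis, key=lambda r: r.pair)
        ],
        columns=["protein_a", "protein_b", "confidence"],
    )
    terms = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "component": r.component,
                "name": r.name,
                "source": r.source,
                "parent_ids": _join(r.parent_ids),
                "pathway_ids": _join(r.pathway_ids),
                "phenotype_ids": _join(r.phenotype_ids),
            }
            for r in sorted(datastore.terms.values(),
                            key=lambda r: (r.component, r.term_id))
        ],
        columns=["term_id", "component", "name", "source", "parent_ids",
                 "pathway_ids", "phenotype_ids"],
    )
    drugs = pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "name": r.name,
                "status": r.status,
                "target_protein_ids": _join(r.target_protein_ids),
                "indication_disease_ids": _join(r.indication_disease_ids),
                "compound_xref": r.compound_xref or "",
            }
            for r in sorted(datastore.drugs.values(), key=lambda r: r.drug_id)
        ],
        columns=["drug_id", "name", "status", "target_protein_ids",
                 "indication_disease_ids", "compound_xref"],
    )
    compounds = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "fingerprint": ",".join(str(b) for b in sorted(r.fingerprint.on_bits)),
                "fp_width": r.fingerprint.width,
            }
            for r in sorted(datastore.compounds.values(), key=lambda r: r.compound_id)
        ],
        columns=["compound_id", "name", "fingerprint", "fp_width"],
    )
    bioactivities = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_protein_id": r.target_protein_id,
                "standard_type": r.standard_type,
                "pchembl": "" if r.pchembl is None else r.pchembl,
                "target_kind": r.target_kind,
                "taxon_id": r.taxon_id,
            }
            for r in sorted(
                datastore.bioactivities,
                key=lambda r: (r.compound_id, r.target_protein_id, r.standard_type,
                               r.pchembl or 0.0),
            )
        ],
        columns=["compound_id", "target_protein_id", "standard_type", "pchembl",
                 "target_kind", "taxon_id"],
    )
    predicted = pd.DataFrame(
        [
            {
                "compound_or_drug_id": r.compound_or_drug_id,
                "target_protein_id": r.target_protein_id,
                "source_model": r.source_model,
                "score": "" if r.score is None else r.score,
            }
            for r in sorted(
                datastore.predicted_dtis,
                key=lambda r: (r.compound_or_drug_id, r.target_protein_id,
                               r.source_model),
            )
        ],
        columns=["compound_or_drug_id", "target_protein_id", "source_model", "score"],
    )
    return {
        "proteins": proteins,
        "ppis": ppis,
        "terms": terms,
        "drugs": drugs,
        "compounds": compounds,
        "bioactivities": bioactivities,
        "predicted_dtis": predicted,
    }
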