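"""Annotated small-protein vector database and KNN label transfer.

Database construction filters an annotated FASTA down to small (<=100 aa),
annotated, non-redundant entries (deduplicated by clustering at 80%
identity), embeds the survivors, and stores EC numbers and taxa parsed from
the headers.  Family representatives are then annotated by their k nearest
database vectors under Euclidean distance with a three-rule heuristic:

1. a unique most-frequent label among neighbors carrying the field wins;
2. on a frequency tie, the label of the nearest tied neighbor wins;
3. if no neighbor carries the field, the query stays UNANNOTATED.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import ClusterParams, align_pair, cluster_linear, passes_thresholds
from .embedding import EmbedderSpec, EmbeddingMatrix, EmbedFn, embed_batch
from .families import SmallProteinFamily
from .io import (
    ProteinRecord,
    parse_uniprot_description,
    read_fasta,
    read_tsv_table,
    write_fasta,
    write_tsv_table,
)

UNANNOTATED = "UNANNOTATED"
UNRESOLVED = "UNRESOLVED"


@dataclass
class DBEntry:
    id: str
    sequence: str
    vector: np.ndarray
    ec_numbers: list[str]
    taxon: str | None
    protein_name: str


@dataclass
class AnnotationDB:
    entries: list[DBEntry]
    embedder: EmbedderSpec
    max_length: int = 100
    dedup_identity: float = 0.8

    @property
    def vectors(self) -> np.ndarray:
        return np.vstack([e.vector for e in self.entries])


@dataclass(frozen=True)
class AnnotatorParams:
    k: int = 10  # ten nearest neighbors recommended for small proteins

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class AnnotationAssignment:
    family_id: str
    field: str  # "EC" or "taxonomy"
    label: str
    support: int
    neighbor_ids: list[str]


def _annotation_rank(name: str, ecs: list[str], taxon: str | None) -> int:
    """Specificity of an annotation: EC beats taxon beats name-only."""
    if ecs:
        return 0
    if taxon:
        return 1
    return 2


def _is_unannotated_name(name: str) -> bool:
    low = name.lower()
    return "uncharacterized" in low or "unannotated" in low


def build_db(
    annotated_records: Sequence[ProteinRecord],
    embedder: EmbedderSpec = EmbedderSpec(),
    max_length: int = 100,
    dedup_identity: float = 0.8,
    adapter: EmbedFn | None = None,
    cluster_params: ClusterParams | None = None,
) -> AnnotationDB:
    """Filter, deduplicate and embed an annotated small-protein source.

    Pipeline: drop records longer than ``max_length``; drop records whose
    name marks them uncharacterized/unannotated (or that carry no annotation
    at all); cluster the rest at ``dedup_identity`` and keep one entry per
    cluster, preferring the most specifically annotated member (EC present >
    taxon present > name only; ties to the longest, then smallest id).
    """
    parsed: dict[str, tuple[str, list[str], str | None]] = {}
    survivors: list[ProteinRecord] = []
    for r in annotated_records:
        if r.length > max_length:
            continue
        name, ecs, taxon = parse_uniprot_description(r.description or "")
        taxon = taxon or r.taxon
        if _is_unannotated_name(name):
            continue
        if not ecs and not taxon and not name:
            continue
        parsed[r.id] = (name, ecs, taxon)
        survivors.append(r)
    if not survivors:
        raise ValueError("build_db: no annotated small proteins survive filtering")

    params = cluster_params or ClusterParams(min_identity=dedup_identity)
    clusters = cluster_linear(survivors, params)
    by_id = {r.id: r for r in survivors}
    reps: list[ProteinRecord] = []
    for cluster in clusters.clusters:
        best = min(
            cluster.member_ids,
            key=lambda mid: (
                _annotation_rank(*parsed[mid]),
                -by_id[mid].length,
                mid,
            ),
        )
        reps.append(by_id[best])
    reps.sort(key=lambda r: r.id)

    matrix = embed_batch(reps, embedder, adapter=adapter)
    entries = []
    for r, vec in zip(reps, matrix.vectors):
        name, ecs, taxon = parsed[r.id]
        entries.append(
            DBEntry(
                id=r.id,
                sequence=r.sequence,
                vector=vec,
                ec_numbers=ecs,
                taxon=taxon,
                protein_name=name,
            )
        )
    return AnnotationDB(
        entries=entries,
        embedder=embedder,
        max_length=max_length,
        dedup_identity=dedup_identity,
    )


def knn(
    db: AnnotationDB, query_vector: np.ndarray, k: int
) -> list[tuple[DBEntry, float]]:
    """The k nearest entries by Euclidean distance, ascending; distance ties
    go to the smallest id; k larger than the database returns everything."""
    query_vector = np.asarray(query_vector, dtype=float)
    vectors = db.vectors
    if query_vector.shape[0] != vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: query {query_vector.shape[0]}, "
            f"db {vectors.shape[1]}"
        )
    dists = np.sqrt(((vectors - query_vector) ** 2).sum(axis=1))
    order = sorted(range(len(db.entries)),
                   key=lambda i: (dists[i], db.entries[i].id))
    return [(db.entries[i], float(dists[i])) for i in order[: min(k, len(order))]]


def assign_annotation(
    family_id: str,
    neighbors: Sequence[tuple[DBEntry, float]],
    field: str,
) -> AnnotationAssignment:
    """Apply the three-rule heuristic to an ordered neighbor list.

    Only neighbors carrying the requested field vote.  A unique modal label
    wins with its count as support; tied modal labels are broken by the
    nearest neighbor among them; no field-carrying neighbor at all yields
    UNANNOTATED with support 0.
    """
    if field not in ("EC", "taxonomy"):
        raise ValueError(f"unknown annotation field {field!r}")

    labeled: list[str] = []  # in ascending-distance order
    for entry, _ in neighbors:
        if field == "EC":
            labels = entry.ec_numbers
        else:
            labels = [entry.taxon] if entry.taxon else []
        if labels:
            labeled.append(labels[0])

    neighbor_ids = [entry.id for entry, _ in neighbors]
    if not labeled:
        return AnnotationAssignment(
            family_id=family_id, field=field, label=UNANNOTATED,
            support=0, neighbor_ids=neighbor_ids,
        )
    counts: dict[str, int] = {}
    for lab in labeled:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    if len(tied) == 1:
        label = next(iter(tied))
    else:
        label = next(lab for lab in labeled if lab in tied)
    return AnnotationAssignment(
        family_id=family_id, field=field, label=label,
        support=counts[label], neighbor_ids=neighbor_ids,
    )


def annotate_families(
    db: AnnotationDB,
    families: Sequence[SmallProteinFamily],
    params: AnnotatorParams = AnnotatorParams(),
    adapter: EmbedFn | None = None,
) -> list[AnnotationAssignment]:
    """KNN-annotate every family representative for both EC and taxonomy."""
    reps = [f.representative for f in families]
    matrix = embed_batch(reps, db.embedder, adapter=adapter)
    out: list[AnnotationAssignment] = []
    for fam, vec in zip(families, matrix.vectors):
        neighbors = knn(db, vec, params.k)
        for fieldname in ("EC", "taxonomy"):
            out.append(assign_annotation(fam.family_id, neighbors, fieldname))
    return out


class LineageTable:
    """taxon -> (rank, parent) lookup loaded from a plain TSV."""

    def __init__(self, rows: dict[str, tuple[str, str | None]]):
        self.rows = rows

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTable":
        rows = {}
        for row in read_tsv_table(path):
            rows[row["taxon"]] = (row["rank"], row.get("parent") or None)
        return cls(rows)


def normalize_taxon_to_family(
    taxon: str, lineage: LineageTable
) -> str:
    """Walk the lineage upward to the family-rank ancestor, if any."""
    current: str | None = taxon
    seen: set[str] = set()
    while current and current not in seen:
        seen.add(current)
        entry = lineage.rows.get(current)
        if entry is None:
            return UNRESOLVED
        rank, parent = entry
        if rank == "family":
            return current
        current = parent
    return UNRESOLVED


def match_known_genes(
    families_per_sample: dict[str, Sequence[SmallProteinFamily]],
    known: Sequence[ProteinRecord],
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
    cluster_params: ClusterParams | None = None,
) -> list[dict]:
    """Search known small genes against family representatives per sample.

    A gene matches a family when the gene-vs-representative alignment reaches
    ``min_identity`` with bidirectional coverage >= ``min_coverage``; its
    copy number in a sample is the summed size of matching families, zero
    when nothing matches.
    """
    params = cluster_params or ClusterParams(
        min_identity=min_identity, min_coverage=min_coverage,
        coverage_mode="bidirectional",
    )
    rows = []
    for sample_id in sorted(families_per_sample):
        families = families_per_sample[sample_id]
        for gene in known:
            total = 0
            for fam in families:
                res = align_pair(gene, fam.representative, params)
                if (res.identity >= min_identity
                        and res.coverage_query >= min_coverage
                        and res.coverage_target >= min_coverage):
                    total += fam.size
            rows.append(
                {"gene_id": gene.id, "sample_id": sample_id,
                 "copy_number": total}
            )
    return rows


def read_external_annotations_tsv(path: str | Path) -> dict[str, dict]:
    """Import annotations produced by an external annotator (e.g. an
    HMM-based tool) for side-by-side comparison tables.

    Expects a TSV with columns ``query`` plus any of ``ec``, ``taxon``;
    multiple ECs separated by ``;``.  Returns query id -> annotation dict.
    Comparison only — external results never feed the KNN assignment.
    """
    out: dict[str, dict] = {}
    for row in read_tsv_table(path):
        out[row["query"]] = {
            "ec_numbers": [e for e in row.get("ec", "").split(";") if e],
            "taxon": row.get("taxon") or None,
        }
    return out


# --- on-disk database -------------------------------------------------------

def save_db(db: AnnotationDB, directory: str | Path) -> None:
    """Persist as FASTA + annotations TSV + embeddings TSV + metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [ProteinRecord(id=e.id, sequence=e.sequence) for e in db.entries],
        directory / "db.fasta",
    )
    write_tsv_table(
        [
            {
                "id": e.id,
                "protein_name": e.protein_name,
                "ec_numbers": ";".join(e.ec_numbers),
                "taxon": e.taxon or "",
            }
            for e in db.entries
        ],
        directory / "annotations.tsv",
        columns=["id", "protein_name", "ec_numbers", "taxon"],
    )
    from .embedding import write_embeddings_tsv

    matrix = EmbeddingMatrix(
        ids=[e.id for e in db.entries],
        vectors=db.vectors,
        embedder=db.embedder,
    )
    write_embeddings_tsv(matrix, directory / "embeddings.tsv")
    meta = {
        "embedder": {
            "name": db.embedder.name,
            "dimension": db.embedder.dimension,
            "seed": db.embedder.seed,
        },
        "max_length": db.max_length,
        "dedup_identity": db.dedup_identity,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_db(directory: str | Path) -> AnnotationDB:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    spec = EmbedderSpec(**meta["embedder"])
    from .embedding import read_embeddings_tsv

    matrix = read_embeddings_tsv(directory / "embeddings.tsv", spec)
    seqs = {r.id: r.sequence for r in read_fasta(directory / "db.fasta")}
    ann = {row["id"]: row for row in read_tsv_table(directory / "annotations.tsv")}
    entries = []
    for rid, vec in zip(matrix.ids, matrix.vectors):
        row = ann[rid]
        entries.append(
            DBEntry(
                id=rid,
                sequence=seqs[rid],
                vector=vec,
                ec_numbers=[e for e in row["ec_numbers"].split(";") if e],
                taxon=row["taxon"] or None,
                protein_name=row["protein_name"],
            )
        )
    return AnnotationDB(
        entries=entries,
        embedder=spec,
        max_length=int(meta["max_length"]),
        dedup_identity=float(meta["dedup_identity"]),
    )


def assignments_table(assignments: Sequence[AnnotationAssignment]) -> list[dict]:
    """Wide per-family rows: EC, EC support, taxonomy, taxonomy support."""
    by_family: dict[str, dict] = {}
    for a in assignments:
        row = by_family.setdefault(
            a.family_id,
            {"family_id": a.family_id, "EC": UNANNOTATED, "EC_support": 0,
             "taxonomy": UNANNOTATED, "tax_support": 0,
             "neighbor_ids": ";".join(a.neighbor_ids)},
        )
        if a.field == "EC":
            row["EC"], row["EC_support"] = a.label, a.support
        else:
            row["taxonomy"], row["tax_support"] = a.label, a.support
    return [by_family[k] for k in sorted(by_family)]
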