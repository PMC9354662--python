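"""End-to-end orchestration: per-sample stages and cross-sample study outputs.

The per-sample flow is clustering -> family calling -> variant observation ->
embedding -> annotation, with every stage's output written before the next
begins so a run can be resumed.  The study step aggregates per-sample results
into the abundance table, the shared-annotation table, the group comparison
and the landscape overlay coordinates.

Protein assembly is a documented external prerequisite: the pipeline's
contract starts at an assembled protein FASTA per sample.  An optional
subprocess hook (a command template in the config) lets users invoke their
assembler, but nothing here imports or requires one.
"""

from __future__ import annotations

import json
import logging
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotation import (
    AnnotationDB,
    AnnotationAssignment,
    AnnotatorParams,
    UNANNOTATED,
    annotate_families,
    assignments_table,
    load_db,
)
from .clustering import (
    ClusterParams,
    cluster_linear,
    read_clusters_tsv,
    write_clusters_tsv,
)
from .embedding import (
    EmbedderSpec,
    EmbeddingMatrix,
    embed_batch,
    fit_landscape,
    project_landscape,
    read_embeddings_tsv,
    write_embeddings_tsv,
)
from .families import FamilyParams, SmallProteinFamily, call_families, family_summary
from .io import (
    ProteinRecord,
    SampleManifest,
    read_fasta,
    read_tsv_table,
    write_fasta,
    write_tsv_table,
)
from .quantify import compare_groups, comparison_table, copy_number_table, restrict_to_shared
from .variants import align_center_star, call_variants, variants_table, write_alignment_fasta

logger = logging.getLogger("smorfscape")


@dataclass
class PipelineConfig:
    outdir: Path
    db_dir: Path | None = None
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    family_params: FamilyParams = field(default_factory=FamilyParams)
    embedder: EmbedderSpec = field(default_factory=EmbedderSpec)
    annotator: AnnotatorParams = field(default_factory=AnnotatorParams)
    resume: bool = False
    threads: int = 1
    assembly_command: str | None = None  # e.g. "plass assemble {reads} {out}"


def run_assembly_hook(config: PipelineConfig, **fields) -> None:
    """Invoke the configured external assembler command, if any."""
    if not config.assembly_command:
        raise ValueError("no assembly_command configured")
    cmd = config.assembly_command.format(**fields)
    logger.info("running external assembly: %s", cmd)
    subprocess.run(cmd, shell=True, check=True)


def _fresh(path: Path, resume: bool) -> bool:
    """True when the stage must run (no resumable output)."""
    return not (resume and path.exists() and path.stat().st_size > 0)


def run_sample(
    entry: SampleManifest,
    config: PipelineConfig,
    db: AnnotationDB | None = None,
) -> dict:
    """Run all per-sample stages; returns paths and in-memory products."""
    sample_dir = Path(config.outdir) / entry.sample_id
    sample_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(entry.path, sample_id=entry.sample_id)
    if not records:
        raise ValueError(f"sample {entry.sample_id}: empty FASTA {entry.path}")
    by_id = {r.id: r for r in records}

    clusters_path = sample_dir / "clusters.tsv"
    if _fresh(clusters_path, config.resume):
        logger.info("[%s] clustering %d records", entry.sample_id, len(records))
        clusters = cluster_linear(records, config.cluster_params)
        write_clusters_tsv(clusters, clusters_path)
    else:
        logger.info("[%s] resume: clustering skipped", entry.sample_id)
        clusters = read_clusters_tsv(clusters_path, config.cluster_params)

    families = call_families(clusters, records, config.family_params)
    reps_path = sample_dir / "family_representatives.fasta"
    summary_path = sample_dir / "family_summary.tsv"
    if _fresh(summary_path, config.resume):
        write_fasta([f.representative for f in families], reps_path)
        write_tsv_table(
            family_summary(families), summary_path,
            columns=["family_id", "size", "representative_length",
                     "n_distinct_sequences"],
        )

    variants_path = sample_dir / "variants.tsv"
    aln_dir = sample_dir / "alignments"
    if _fresh(variants_path, config.resume):
        aln_dir.mkdir(exist_ok=True)
        variant_rows: list[dict] = []
        for fam in families:
            alignment = align_center_star(fam, config.cluster_params)
            write_alignment_fasta(alignment, aln_dir / f"{_safe(fam.family_id)}.afa")
            variant_rows.extend(
                variants_table(fam.family_id, call_variants(alignment))
            )
        write_tsv_table(
            variant_rows, variants_path,
            columns=["family_id", "column", "consensus_residue", "alternate",
                     "count", "conservation"],
        )

    emb_path = sample_dir / "embeddings.tsv"
    if _fresh(emb_path, config.resume):
        matrix = embed_batch(
            [f.representative for f in families], config.embedder,
            n_workers=config.threads,
        )
        write_embeddings_tsv(matrix, emb_path)
    else:
        matrix = read_embeddings_tsv(emb_path, config.embedder)

    assignments: list[AnnotationAssignment] = []
    ann_path = sample_dir / "annotations.tsv"
    if db is None and config.db_dir is not None:
        db = load_db(config.db_dir)
    if db is not None:
        assignments = annotate_families(db, families, config.annotator)
        write_tsv_table(
            assignments_table(assignments), ann_path,
            columns=["family_id", "EC", "EC_support", "taxonomy",
                     "tax_support", "neighbor_ids"],
        )

    run_manifest = {
        "version": __version__,
        "sample_id": entry.sample_id,
        "n_records": len(records),
        "n_families": len(families),
        "params": {
            "cluster": vars(config.cluster_params).copy(),
            "family": vars(config.family_params).copy(),
            "embedder": vars(config.embedder).copy(),
            "annotator": vars(config.annotator).copy(),
        },
    }
    (sample_dir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True)
    )
    return {
        "sample_dir": sample_dir,
        "records": records,
        "families": families,
        "assignments": assignments,
        "embeddings": matrix,
    }


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def run_study(
    manifest: Sequence[SampleManifest],
    config: PipelineConfig,
    db: AnnotationDB | None = None,
) -> dict:
    """Run every sample, then aggregate cross-sample study outputs."""
    if db is None and config.db_dir is not None:
        db = load_db(config.db_dir)
    per_sample = {}
    for entry in manifest:
        per_sample[entry.sample_id] = run_sample(entry, config, db=db)

    outdir = Path(config.outdir)
    families = {s: r["families"] for s, r in per_sample.items()}
    assignments = {s: r["assignments"] for s, r in per_sample.items()}

    results: dict = {"per_sample": per_sample}
    if db is not None:
        table = copy_number_table(assignments, families, field="EC")
        table.to_csv(outdir / "abundance_ec.tsv", sep="\t")
        shared = restrict_to_shared(table)
        shared.to_csv(outdir / "abundance_ec_shared.tsv", sep="\t")
        results["abundance"] = table
        results["shared"] = shared

        groups = {
            e.sample_id: e.group for e in manifest if e.group is not None
        }
        if len(set(groups.values())) >= 2 and not shared.empty:
            comparisons = compare_groups(shared, groups)
            write_tsv_table(
                comparison_table(comparisons), outdir / "group_comparison.tsv"
            )
            results["comparisons"] = comparisons

        # landscape: fit on the database, overlay every sample's families
        db_matrix = EmbeddingMatrix(
            ids=[e.id for e in db.entries], vectors=db.vectors,
            embedder=db.embedder,
        )
        if len(db.entries) >= 3:
            model = fit_landscape(db_matrix)
            overlay_rows = []
            for sample_id in sorted(per_sample):
                coords = project_landscape(model, per_sample[sample_id]["embeddings"])
                overlay_rows.extend(
                    {"sample_id": sample_id, "family_id": fid,
                     "x": repr(x), "y": repr(y)}
                    for fid, x, y in coords
                )
            write_tsv_table(
                overlay_rows, outdir / "landscape_overlay.tsv",
                columns=["sample_id", "family_id", "x", "y"],
            )
            results["landscape"] = model
    return results
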