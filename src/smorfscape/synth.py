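"""Synthetic communities and annotation sources with full ground truth.

The generator emulates the statistical structure the pipeline assumes:
homologous small-protein families as point-mutated copies of a random
ancestor (independent per-residue substitutions, like the random-mutation
validation of clustering tolerance), optional prefix truncations at a stated
retained-length fraction, abundant long proteins, singleton noise sequences,
and an annotated database source with EC numbers, taxa and planted decoys.

Everything is driven by one integer seed and is byte-deterministic; the
emitted Truth object carries per-record family assignments, planted mutation
positions, per-family labels, and the expected copies-per-million table so
tests can compare pipeline output against exact expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    ProteinRecord,
    SampleManifest,
    write_fasta,
    write_manifest,
    write_tsv_table,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: small pool of realistic labels planted on synthetic families
EC_POOL = [
    "1.11.1.6", "2.7.7.7", "2.7.13.3", "3.2.1.4", "3.5.1.5",
    "4.2.1.2", "5.3.1.9", "6.3.2.6", "1.1.1.1", "2.3.1.12",
]
TAXON_POOL = [
    ("Blautia producta", "Lachnospiraceae"),
    ("Faecalibacterium prausnitzii", "Oscillospiraceae"),
    ("Clostridium butyricum", "Clostridiaceae"),
    ("Escherichia coli", "Enterobacteriaceae"),
    ("Bacillus subtilis", "Bacillaceae"),
]


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_families: int = 10
    family_size: tuple[int, int] = (4, 8)
    length_range: tuple[int, int] = (30, 100)
    mutation_rate: float = 0.02
    truncation_fraction: float = 0.0
    truncation_retained: float = 0.9
    n_long_proteins: int = 5
    long_length_range: tuple[int, int] = (120, 300)
    n_singletons: int = 10
    annotation_fraction: float = 1.0
    # multi-sample study structure
    n_samples: int = 1
    groups: tuple[str, ...] = ()  # one label per sample; empty -> no groups
    enriched_ec: str | None = None  # this EC's families get size x factor ...
    enriched_group: str | None = None  # ... in samples of this group
    enrichment_factor: float = 3.0
    # annotation-source structure
    db_entries_per_family: int = 3
    db_mutation_rate: float = 0.01
    n_uncharacterized_decoys: int = 0
    n_long_decoys: int = 0


@dataclass
class Truth:
    """Ground-truth bookkeeping for a generated community."""

    record_family: dict[tuple[str, str], str]  # (sample, record id) -> family
    mutation_positions: dict[tuple[str, str], list[int]]  # 1-based, ancestor coords
    family_ancestor: dict[str, str]  # family id -> ancestor sequence
    family_ec: dict[str, str | None]
    family_taxon: dict[str, str | None]
    family_sizes: dict[str, dict[str, int]]  # sample -> family -> copies
    expected_c: dict[str, dict[str, float]]  # sample -> EC -> copies/million


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(
    rng: np.random.Generator, sequence: str, rate: float
) -> tuple[str, list[int]]:
    """Independent per-residue substitutions to a uniformly random different
    residue; returns the mutant and the 1-based positions actually changed."""
    residues = list(sequence)
    positions = []
    hits = rng.random(len(residues)) < rate
    for i in np.flatnonzero(hits):
        current = residues[i]
        choices = [a for a in _AA if a != current]
        residues[i] = choices[rng.integers(len(choices))]
        positions.append(int(i) + 1)
    return "".join(residues), positions


def make_family(
    config: SynthConfig,
    rng: np.random.Generator,
    family_id: str = "f000",
    size: int | None = None,
    ancestor: str | None = None,
    sample_id: str = "",
) -> tuple[list[ProteinRecord], dict[str, list[int]], str]:
    """Emit one homologous family: ``size`` mutated copies of an ancestor,
    a configured fraction of them as prefix truncations.

    Returns (records, planted mutation positions per record id, ancestor).
    """
    lo, hi = config.length_range
    if ancestor is None:
        ancestor = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
    if size is None:
        size = int(rng.integers(config.family_size[0], config.family_size[1] + 1))
    n_trunc = int(round(config.truncation_fraction * size))
    records = []
    mutations: dict[str, list[int]] = {}
    for j in range(size):
        seq, positions = _mutate(rng, ancestor, config.mutation_rate)
        rid = f"{family_id}m{j:02d}"
        if j >= size - n_trunc:
            # ceil so the fragment retains at least the stated fraction
            keep = max(1, math.ceil(config.truncation_retained * len(seq)))
            seq = seq[:keep]
            positions = [p for p in positions if p <= keep]
            rid += "t"
        records.append(ProteinRecord(id=rid, sequence=seq, sample_id=sample_id))
        mutations[rid] = positions
    return records, mutations, ancestor


def _sample_groups(config: SynthConfig) -> list[str | None]:
    if config.groups:
        if len(config.groups) != config.n_samples:
            raise ValueError("groups must have one label per sample")
        return list(config.groups)
    return [None] * config.n_samples


def make_community(
    config: SynthConfig, outdir: str | Path | None = None
) -> tuple[list[SampleManifest], dict[str, list[ProteinRecord]], Truth]:
    """Generate a multi-sample community with shared family ancestors.

    Every sample contains every family (so shared-annotation filtering keeps
    them all), with per-sample copy numbers drawn from ``family_size``; when
    ``enriched_ec`` is set, families carrying that EC have their copy number
    scaled by ``enrichment_factor`` in samples of ``enriched_group``.  Long
    proteins and singleton noise are unique per sample.  If ``outdir`` is
    given, FASTA files, a manifest TSV and truth TSVs are written there.
    """
    rng = np.random.default_rng(config.seed)
    groups = _sample_groups(config)

    # global family panel
    families = [f"f{i:03d}" for i in range(config.n_families)]
    family_ancestor: dict[str, str] = {}
    family_ec: dict[str, str | None] = {}
    family_taxon: dict[str, str | None] = {}
    lo, hi = config.length_range
    for i, fid in enumerate(families):
        family_ancestor[fid] = _random_sequence(
            rng, int(rng.integers(lo, hi + 1))
        )
        if rng.random() < config.annotation_fraction:
            family_ec[fid] = EC_POOL[i % len(EC_POOL)]
            family_taxon[fid] = TAXON_POOL[i % len(TAXON_POOL)][0]
        else:
            family_ec[fid] = None
            family_taxon[fid] = None
    if config.enriched_ec is not None and config.enriched_ec not in family_ec.values():
        # guarantee the planted effect has a carrier
        family_ec[families[0]] = config.enriched_ec

    record_family: dict[tuple[str, str], str] = {}
    mutation_positions: dict[tuple[str, str], list[int]] = {}
    family_sizes: dict[str, dict[str, int]] = {}
    samples: dict[str, list[ProteinRecord]] = {}
    manifest: list[SampleManifest] = []

    for s_idx in range(config.n_samples):
        sample_id = f"s{s_idx:02d}"
        group = groups[s_idx]
        records: list[ProteinRecord] = []
        sizes: dict[str, int] = {}
        for fid in families:
            size = int(
                rng.integers(config.family_size[0], config.family_size[1] + 1)
            )
            if (
                config.enriched_ec is not None
                and family_ec[fid] == config.enriched_ec
                and group == config.enriched_group
            ):
                size = int(round(size * config.enrichment_factor))
            fam_records, fam_mut, _ = make_family(
                config, rng, family_id=fid, size=size,
                ancestor=family_ancestor[fid], sample_id=sample_id,
            )
            records.extend(fam_records)
            sizes[fid] = size
            for rid, pos in fam_mut.items():
                record_family[(sample_id, rid)] = fid
                mutation_positions[(sample_id, rid)] = pos
        llo, lhi = config.long_length_range
        for i in range(config.n_long_proteins):
            records.append(
                ProteinRecord(
                    id=f"long{i:03d}",
                    sequence=_random_sequence(rng, int(rng.integers(llo, lhi + 1))),
                    sample_id=sample_id,
                )
            )
        for i in range(config.n_singletons):
            records.append(
                ProteinRecord(
                    id=f"noise{i:03d}",
                    sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                    sample_id=sample_id,
                )
            )
        perm = rng.permutation(len(records))
        records = [records[i] for i in perm]
        samples[sample_id] = records
        family_sizes[sample_id] = sizes
        manifest.append(
            SampleManifest(
                sample_id=sample_id,
                path=Path(f"{sample_id}.fasta"),
                group=group,
            )
        )

    expected_c: dict[str, dict[str, float]] = {}
    for sample_id, sizes in family_sizes.items():
        denom = sum(sizes.values())
        col: dict[str, float] = {}
        for fid, size in sizes.items():
            ec = family_ec[fid]
            if ec is None:
                continue
            col[ec] = col.get(ec, 0.0) + size
        expected_c[sample_id] = {
            ec: total * 1_000_000 / denom for ec, total in col.items()
        }

    truth = Truth(
        record_family=record_family,
        mutation_positions=mutation_positions,
        family_ancestor=family_ancestor,
        family_ec=family_ec,
        family_taxon=family_taxon,
        family_sizes=family_sizes,
        expected_c=expected_c,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for entry in manifest:
            entry.path = outdir / entry.path.name
            write_fasta(samples[entry.sample_id], entry.path)
        # manifest paths stay relative to the manifest itself, so a generated
        # study directory is relocatable and byte-identical across runs
        relative = [
            SampleManifest(sample_id=e.sample_id, path=Path(e.path.name),
                           group=e.group)
            for e in manifest
        ]
        write_manifest(relative, outdir / "manifest.tsv")
        write_truth(truth, outdir)
    return manifest, samples, truth


def make_annotation_source(config: SynthConfig) -> tuple[list[ProteinRecord], Truth]:
    """Annotated FASTA records for database building, derived from the same
    family panel as :func:`make_community` under the same seed.

    Each annotated family contributes ``db_entries_per_family`` near-copies
    of its ancestor with Uniprot-style headers carrying its EC and taxon.
    Planted decoys — "Uncharacterized protein" entries and over-length
    entries — exercise the database filters.
    """
    _, _, truth = make_community(config)
    rng = np.random.default_rng(config.seed + 1)
    records: list[ProteinRecord] = []
    for fid in sorted(truth.family_ancestor):
        ec = truth.family_ec[fid]
        taxon = truth.family_taxon[fid]
        if ec is None and taxon is None:
            continue
        parts = [f"Synthetic protein {fid}"]
        if ec:
            parts.append(f"EC={ec}")
        if taxon:
            parts.append(f"OS={taxon} OX=0")
        description = " ".join(parts)
        for j in range(config.db_entries_per_family):
            seq, _ = _mutate(rng, truth.family_ancestor[fid], config.db_mutation_rate)
            records.append(
                ProteinRecord(
                    id=f"syn|{fid.upper()}D{j}|{fid.upper()}_SYN",
                    sequence=seq,
                    description=description,
                    taxon=taxon,
                )
            )
    lo, hi = config.length_range
    for i in range(config.n_uncharacterized_decoys):
        records.append(
            ProteinRecord(
                id=f"syn|DECOYU{i:03d}|DECOY_SYN",
                sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                description="Uncharacterized protein OS=uncultured bacterium OX=0",
                taxon="uncultured bacterium",
            )
        )
    llo, lhi = config.long_length_range
    for i in range(config.n_long_decoys):
        records.append(
            ProteinRecord(
                id=f"syn|DECOYL{i:03d}|DECOY_SYN",
                sequence=_random_sequence(rng, int(rng.integers(max(llo, 101), lhi + 1))),
                description=f"Synthetic long decoy EC=9.9.9.9 OS=Escherichia coli OX=562",
            )
        )
    return records, truth


def lineage_rows() -> list[dict]:
    """A small species -> genus-free -> family lineage for the taxon pool."""
    rows = []
    for species, family in TAXON_POOL:
        rows.append({"taxon": species, "rank": "species", "parent": family})
        rows.append({"taxon": family, "rank": "family", "parent": "Bacteria"})
    rows.append({"taxon": "Bacteria", "rank": "superkingdom", "parent": ""})
    return rows


def write_truth(truth: Truth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    write_tsv_table(
        [
            {
                "sample_id": s,
                "record_id": r,
                "family_id": fid,
                "mutation_positions": ";".join(
                    str(p) for p in truth.mutation_positions[(s, r)]
                ),
            }
            for (s, r), fid in sorted(truth.record_family.items())
        ],
        outdir / "truth_records.tsv",
        columns=["sample_id", "record_id", "family_id", "mutation_positions"],
    )
    write_tsv_table(
        [
            {
                "family_id": fid,
                "ancestor": truth.family_ancestor[fid],
                "ec": truth.family_ec[fid] or "",
                "taxon": truth.family_taxon[fid] or "",
            }
            for fid in sorted(truth.family_ancestor)
        ],
        outdir / "truth_families.tsv",
        columns=["family_id", "ancestor", "ec", "taxon"],
    )
    write_tsv_table(
        [
            {"sample_id": s, "ec": ec, "expected_c": repr(v)}
            for s in sorted(truth.expected_c)
            for ec, v in sorted(truth.expected_c[s].items())
        ],
        outdir / "truth_expected_c.tsv",
        columns=["sample_id", "ec", "expected_c"],
    )
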