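"""Domain records and readers/writers for the formats the pipeline touches.

Protein sequences travel as :class:`ProteinRecord`; everything tabular is a
plain list of dicts written through :func:`write_tsv_table` (pandas under the
hood) so that every stage output round-trips bit-exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues silently widened to X; everything else is rejected
AMBIGUOUS_AA = set("BZUO")

_EC_PATTERNS = (
    re.compile(r"EC=(\d+\.[\d-]+\.[\d-]+\.[\d-]+)"),
    re.compile(r"\(EC\s+(\d+\.[\d-]+\.[\d-]+\.[\d-]+)\)"),
)
_OS_PATTERN = re.compile(r"OS=(.+?)(?:\s+(?:OX|GN|PE|SV)=|$)")


@dataclass
class ProteinRecord:
    """One assembled or database protein sequence.

    ``description`` and ``taxon`` are populated for database records parsed
    from Uniprot-style headers; assembled proteins usually carry only an id,
    a sequence and the sample they came from.
    """

    id: str
    sequence: str
    sample_id: str = ""
    description: str | None = None
    taxon: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ProteinRecord {self.id!r}: empty sequence")


@dataclass
class SampleManifest:
    """One row of the study manifest: a sample id, its protein FASTA, and an
    optional group label (e.g. a diet or condition) for group comparison."""

    sample_id: str
    path: Path
    group: str | None = None


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().strip("*")
    cleaned = []
    warned = False
    for pos, ch in enumerate(seq, start=1):
        if ch in CANONICAL_AA or ch == "X":
            cleaned.append(ch)
        elif ch in AMBIGUOUS_AA:
            if not warned:
                warnings.warn(
                    f"record {record_id!r}: ambiguous residue {ch!r} mapped to X"
                )
                warned = True
            cleaned.append("X")
        else:
            raise ValueError(
                f"record {record_id!r}: non-amino-acid character {ch!r} "
                f"at position {pos}"
            )
    return "".join(cleaned)


def read_fasta(path: str | Path, sample_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into records, in file order.

    The header token before the first whitespace becomes the id, the
    remainder the description.  Lowercase residues are uppercased, terminal
    ``*`` stop characters stripped, B/Z/U/O widened to X with a warning.
    A taxon is extracted from an ``OS=`` field when present.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        description = entry.description[len(entry.id):].strip() or None
        taxon = None
        if description:
            _, _, taxon = parse_uniprot_description(description)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=_normalize_sequence(str(entry.seq), entry.id),
                sample_id=sample_id,
                description=description,
                taxon=taxon,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, ids and sequences only plus any description."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def parse_uniprot_description(
    description: str,
) -> tuple[str, list[str], str | None]:
    """Split a Uniprot-style description into (protein name, EC numbers, taxon).

    EC numbers are matched as ``EC=d.d.d.d`` or ``(EC d.d.d.d)`` (partial ECs
    with ``-`` allowed); the taxon is the ``OS=`` field up to the next keyed
    field.  Absent fields come back empty; the name is the description with
    EC/OS/OX/GN/PE/SV fields removed.
    """
    if not description:
        return "", [], None
    ecs: list[str] = []
    for pat in _EC_PATTERNS:
        ecs.extend(pat.findall(description))
    m = _OS_PATTERN.search(description)
    taxon = m.group(1).strip() if m else None

    name = description
    for pat in _EC_PATTERNS:
        name = pat.sub("", name)
    name = re.sub(r"OS=.*$", "", name)
    name = re.sub(r"\s+(?:OX|GN|PE|SV)=\S*", "", name)
    name = re.sub(r"\s+", " ", name).strip()
    return name, ecs, taxon


def write_tsv_table(rows: Sequence[dict], path: str | Path,
                    columns: Sequence[str] | None = None) -> None:
    """Write uniform records as a TSV with a header line.

    With no rows, ``columns`` supplies the header; the output round-trips
    through :func:`read_tsv_table` bit-exactly for string/int/float fields.
    """
    if rows:
        cols = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != cols:
                raise ValueError("write_tsv_table: rows have differing fields")
        df = pd.DataFrame(rows, columns=cols)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, sep="\t", index=False)


def read_tsv_table(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")


def read_manifest(path: str | Path) -> list[SampleManifest]:
    """Read a manifest TSV with columns sample_id, path and optional group."""
    rows = read_tsv_table(path)
    manifest = []
    seen: set[str] = set()
    base = Path(path).parent
    for row in rows:
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r} in manifest")
        seen.add(sid)
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        manifest.append(
            SampleManifest(sample_id=sid, path=p, group=row.get("group") or None)
        )
    return manifest


def write_manifest(entries: Sequence[SampleManifest], path: str | Path) -> None:
    write_tsv_table(
        [
            {"sample_id": e.sample_id, "path": str(e.path), "group": e.group or ""}
            for e in entries
        ],
        path,
        columns=["sample_id", "path", "group"],
    )
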