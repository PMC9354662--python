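"""Per-family multiple alignment, consensus, and variant-site observation.

Families are near-identical by construction (members passed a high identity
threshold against their representative), so a center-star alignment — every
member aligned pairwise to the representative, merged under "once a gap,
always a gap" — is adequate and dependency-free.  Variant sites are alignment
columns where at least ``min_minor_count`` members differ from the modal
symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .clustering import ClusterParams, align_pair, _MATRICES
from .families import SmallProteinFamily
from .io import ProteinRecord

import biotite.sequence as bseq
import biotite.sequence.align as balign

GAP = "-"


@dataclass
class ClusterAlignment:
    family_id: str
    rows: list[tuple[str, str]]  # (member_id, gapped sequence)
    consensus: str  # per-column modal symbol, may contain gaps
    column_conservation: list[float]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


@dataclass
class VariantSite:
    column: int  # 1-based alignment column
    consensus_residue: str
    alternates: list[tuple[str, int]]
    conservation: float


def _pairwise_to_center(member: ProteinRecord, center: ProteinRecord,
                        params: ClusterParams) -> tuple[list[int], dict[int, list[str]]]:
    """Align member to center; return per-center-position member residue
    indices (-1 for gap) and insertions (member residues falling into center
    gaps), keyed by the center position they precede."""
    matrix = _MATRICES[params.substitution_matrix]
    aln = balign.align_optimal(
        bseq.ProteinSequence(member.sequence),
        bseq.ProteinSequence(center.sequence),
        matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        terminal_penalty=True,
        max_number=1,
    )[0]
    at_center = [-1] * len(center.sequence)
    insertions: dict[int, list[str]] = {}
    next_center = 0
    for mi, ci in aln.trace:
        if ci == -1:
            insertions.setdefault(next_center, []).append(member.sequence[mi])
        else:
            next_center = ci + 1
            if mi != -1:
                at_center[ci] = mi
    return at_center, insertions


def align_center_star(
    family: SmallProteinFamily, params: ClusterParams = ClusterParams()
) -> ClusterAlignment:
    """Center-star multiple alignment of a family around its representative."""
    if family.size < 2:
        raise ValueError(f"family {family.family_id}: nothing to align (size 1)")
    center = family.representative
    others = [m for m in family.members if m.id != center.id]
    pairwise = {m.id: _pairwise_to_center(m, center, params) for m in others}

    n_center = len(center.sequence)
    ins_len = [0] * (n_center + 1)
    for _, insertions in pairwise.values():
        for pos, residues in insertions.items():
            ins_len[pos] = max(ins_len[pos], len(residues))

    def build_row(at_center: list[int], insertions: dict[int, list[str]],
                  sequence: str) -> str:
        parts = []
        for pos in range(n_center + 1):
            ins = insertions.get(pos, [])
            parts.append("".join(ins) + GAP * (ins_len[pos] - len(ins)))
            if pos < n_center:
                mi = at_center[pos]
                parts.append(sequence[mi] if mi != -1 else GAP)
        return "".join(parts)

    rows = [(center.id,
             build_row(list(range(n_center)), {}, center.sequence))]
    for m in others:
        at_center, insertions = pairwise[m.id]
        rows.append((m.id, build_row(at_center, insertions, m.sequence)))
    rows = [rows[0]] + sorted(rows[1:], key=lambda r: r[0])

    consensus, conservation = _column_consensus(rows)
    return ClusterAlignment(
        family_id=family.family_id,
        rows=rows,
        consensus=consensus,
        column_conservation=conservation,
    )


def _column_consensus(rows: list[tuple[str, str]]) -> tuple[str, list[float]]:
    """Modal symbol per column; ties prefer the representative's symbol
    (row 0), then any residue over the gap, then the alphabetically first."""
    n = len(rows[0][1])
    size = len(rows)
    consensus = []
    conservation = []
    for col in range(n):
        symbols = [row[1][col] for row in rows]
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        tied = [s for s, c in counts.items() if c == top]
        if symbols[0] in tied:
            modal = symbols[0]
        else:
            modal = min(tied, key=lambda s: (s == GAP, s))
        consensus.append(modal)
        conservation.append(top / size)
    return "".join(consensus), conservation


def call_variants(
    alignment: ClusterAlignment, min_minor_count: int = 1
) -> list[VariantSite]:
    """Columns where at least ``min_minor_count`` rows differ from the mode."""
    sites = []
    size = len(alignment.rows)
    for col in range(alignment.n_columns):
        symbols = [row[1][col] for row in alignment.rows]
        modal = alignment.consensus[col]
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        minors = size - counts.get(modal, 0)
        if minors >= min_minor_count:
            alternates = sorted(
                ((s, c) for s, c in counts.items() if s != modal),
                key=lambda sc: (-sc[1], sc[0]),
            )
            sites.append(
                VariantSite(
                    column=col + 1,
                    consensus_residue=modal,
                    alternates=alternates,
                    conservation=counts.get(modal, 0) / size,
                )
            )
    return sites


def consensus_sequence(alignment: ClusterAlignment) -> ProteinRecord:
    """Ungapped consensus: modal residues, gap-modal columns dropped."""
    residues = [c for c in alignment.consensus if c != GAP]
    return ProteinRecord(
        id=f"{alignment.family_id}|consensus", sequence="".join(residues)
    )


def align_with_external(
    family: SmallProteinFamily, command: str = "mafft --quiet {input}"
) -> ClusterAlignment:
    """Optional hook: align a family with an external command-line aligner.

    The command template receives ``{input}`` (a FASTA of the members) and
    must print aligned FASTA on stdout.  Row order is normalized to
    representative-first; consensus and conservation are computed the same
    way as for the built-in center-star alignment.
    """
    import subprocess
    import tempfile

    if family.size < 2:
        raise ValueError(f"family {family.family_id}: nothing to align (size 1)")
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for m in family.members:
            fh.write(f">{m.id}\n{m.sequence}\n")
        input_path = fh.name
    try:
        out = subprocess.run(
            command.format(input=input_path), shell=True, check=True,
            capture_output=True, text=True,
        ).stdout
    finally:
        Path(input_path).unlink(missing_ok=True)
    rows_by_id: dict[str, str] = {}
    current = None
    for line in out.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            rows_by_id[current] = ""
        elif current is not None:
            rows_by_id[current] += line.strip().upper()
    rep = family.representative.id
    rows = [(rep, rows_by_id[rep])] + [
        (mid, rows_by_id[mid]) for mid in sorted(rows_by_id) if mid != rep
    ]
    for mid, gapped in rows:
        member = next(m for m in family.members if m.id == mid)
        if gapped.replace(GAP, "") != member.sequence:
            raise ValueError(f"external aligner altered sequence {mid!r}")
    consensus, conservation = _column_consensus(rows)
    return ClusterAlignment(
        family_id=family.family_id, rows=rows, consensus=consensus,
        column_conservation=conservation,
    )


def write_alignment_fasta(alignment: ClusterAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for member_id, gapped in alignment.rows:
            fh.write(f">{member_id}\n{gapped}\n")


def variants_table(
    family_id: str, sites: Sequence[VariantSite]
) -> list[dict]:
    """Long-format rows: one per (site, alternate residue)."""
    rows = []
    for site in sites:
        for residue, count in site.alternates:
            rows.append(
                {
                    "family_id": family_id,
                    "column": site.column,
                    "consensus_residue": site.consensus_residue,
                    "alternate": residue,
                    "count": count,
                    "conservation": round(site.conservation, 6),
                }
            )
    return rows
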