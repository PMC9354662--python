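"""Linear-time greedy protein clustering with min-hash k-mer anchoring.

The procedure mirrors the Linclust idea: every sequence nominates its m
smallest-hash k-mers; sequences sharing a selected k-mer form a group whose
longest member becomes the group centre; each sequence is then verified by
full pairwise alignment against at most m centres and joins the best passing
one.  Runtime is linear in the number of sequences because each sequence
triggers a bounded number of alignments, independent of the input size.

A brute-force all-pairs variant (:func:`cluster_bruteforce`) serves as the
testing oracle on small inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .io import ProteinRecord, write_tsv_table, read_tsv_table

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()
_MATRICES = {"BLOSUM62": _BLOSUM62}


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the greedy clustering.

    ``min_identity`` 0.8 follows the recommended redundancy setting for
    protein-level assemblies; ``min_coverage`` 0.8 bidirectional is the
    default stringency under which ~90%-length fragments still join their
    full-length version while half-length fragments do not.  Lowering
    ``min_coverage`` to 0.5 rescues strong truncations.
    """

    k: int = 10
    m: int = 20
    min_identity: float = 0.8
    min_coverage: float = 0.8
    coverage_mode: str = "bidirectional"  # bidirectional | target | query
    hash_seed: int = 0
    gap_open: int = 11
    gap_extend: int = 1
    substitution_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValueError("k and m must be positive")
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must lie in [0,1]")
        if self.coverage_mode not in ("bidirectional", "target", "query"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


@dataclass
class PairwiseResult:
    identity: float
    coverage_query: float
    coverage_target: float
    score: int


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    params: ClusterParams

    def membership(self) -> dict[str, str]:
        """Map member id -> representative id."""
        return {
            m: c.representative_id for c in self.clusters for m in c.member_ids
        }


def _hash_kmer(kmer: str, seed: int) -> int:
    key = (seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
    digest = hashlib.blake2b(kmer.encode(), digest_size=8, key=key).digest()
    return int.from_bytes(digest, "little")


def select_kmers(record: ProteinRecord, params: ClusterParams) -> set[tuple[str, int]]:
    """The min(m, #distinct) k-mers of the sequence with smallest seeded hash.

    Sequences shorter than k contribute no k-mers and end up as singletons
    unless another sequence's groups absorb them.
    """
    seq = record.sequence
    if len(seq) < params.k:
        return set()
    kmers = {seq[i : i + params.k] for i in range(len(seq) - params.k + 1)}
    hashed = sorted(
        ((_hash_kmer(km, params.hash_seed), km) for km in kmers)
    )
    return {(km, h) for h, km in hashed[: params.m]}


def align_pair(
    query: ProteinRecord, target: ProteinRecord, params: ClusterParams
) -> PairwiseResult:
    """Global affine-gap alignment of query against target.

    Identity is identical columns over aligned (non-gap-in-both) columns;
    coverage of each sequence is its fraction of residues inside aligned
    columns, so terminal truncations lower coverage, not identity.
    """
    matrix = _MATRICES[params.substitution_matrix]
    s_q = bseq.ProteinSequence(query.sequence)
    s_t = bseq.ProteinSequence(target.sequence)
    aln = balign.align_optimal(
        s_q,
        s_t,
        matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        terminal_penalty=True,
        max_number=1,
    )[0]
    trace = aln.trace
    qi, ti = trace[:, 0], trace[:, 1]
    aligned = (qi != -1) & (ti != -1)
    n_aligned = int(aligned.sum())
    if n_aligned:
        q_arr = query.sequence
        t_arr = target.sequence
        identical = sum(
            1
            for a, b, ok in zip(qi, ti, aligned)
            if ok and q_arr[a] == t_arr[b]
        )
        identity = identical / n_aligned
    else:
        identity = 0.0
    return PairwiseResult(
        identity=identity,
        coverage_query=n_aligned / len(query.sequence),
        coverage_target=n_aligned / len(target.sequence),
        score=int(aln.score),
    )


def passes_thresholds(result: PairwiseResult, params: ClusterParams) -> bool:
    if result.identity < params.min_identity:
        return False
    if params.coverage_mode == "bidirectional":
        return (
            result.coverage_query >= params.min_coverage
            and result.coverage_target >= params.min_coverage
        )
    if params.coverage_mode == "target":
        return result.coverage_target >= params.min_coverage
    return result.coverage_query >= params.min_coverage


def _check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


def _elect(ids: Iterable[str], length_of: dict[str, int]) -> str:
    """Longest record wins; ties go to the lexicographically smallest id."""
    return min(ids, key=lambda i: (-length_of[i], i))


def _make_cluster_set(
    assignment: dict[str, str],
    length_of: dict[str, int],
    params: ClusterParams,
) -> ClusterSet:
    groups: dict[str, list[str]] = {}
    for rid, root in assignment.items():
        groups.setdefault(root, []).append(rid)
    clusters = []
    for members in groups.values():
        rep = _elect(members, length_of)
        ordered = [rep] + sorted(m for m in members if m != rep)
        clusters.append(Cluster(representative_id=rep, member_ids=ordered))
    clusters.sort(key=lambda c: c.representative_id)
    return ClusterSet(clusters=clusters, params=params)


def cluster_linear(
    records: Sequence[ProteinRecord], params: ClusterParams = ClusterParams()
) -> ClusterSet:
    """Greedy linear-time clustering.

    1. every record selects its min-hash k-mers;
    2. records sharing a k-mer form a group; the longest (tie: smallest id)
       is the group centre;
    3. each record is alignment-verified against the centres of its groups
       and joins the passing centre with the highest score (tie: smallest
       centre id); records passing none become singletons;
    4. centre chains are flattened to a fixpoint (a centre that itself
       joined another centre drags its members along), cycles broken by
       smallest id.

    Deterministic given the hash seed, and independent of input order.
    """
    _check_unique_ids(records)
    by_id = {r.id: r for r in records}
    length_of = {r.id: r.length for r in records}

    kmer_members: dict[str, list[str]] = {}
    record_kmers: dict[str, list[str]] = {}
    for r in sorted(records, key=lambda r: r.id):
        kms = sorted(km for km, _ in select_kmers(r, params))
        record_kmers[r.id] = kms
        for km in kms:
            kmer_members.setdefault(km, []).append(r.id)

    centre_of_kmer = {
        km: _elect(ids, length_of) for km, ids in kmer_members.items()
    }

    assignment: dict[str, str] = {}
    aln_cache: dict[tuple[str, str], PairwiseResult] = {}
    for rid in sorted(by_id):
        candidates = sorted({centre_of_kmer[km] for km in record_kmers[rid]})
        best: tuple[int, str] | None = None
        for cid in candidates:
            if cid == rid:
                continue  # self never competes; fallback below
            key = (rid, cid)
            res = aln_cache.get(key)
            if res is None:
                res = align_pair(by_id[rid], by_id[cid], params)
                aln_cache[key] = res
            if passes_thresholds(res, params):
                cand = (-res.score, cid)
                if best is None or cand < best:
                    best = cand
        assignment[rid] = best[1] if best is not None else rid

    # flatten centre chains: follow joined-centre pointers to a fixpoint,
    # breaking any cycle at its smallest id
    def resolve(cid: str) -> str:
        path = [cid]
        seen = {cid}
        while assignment[path[-1]] != path[-1]:
            nxt = assignment[path[-1]]
            if nxt in seen:
                cycle_start = path.index(nxt)
                root = min(path[cycle_start:])
                break
            path.append(nxt)
            seen.add(nxt)
        else:
            root = path[-1]
        return root

    roots = {rid: resolve(assignment[rid]) for rid in assignment}
    for rid in roots:  # fixpoint check
        assert roots[rid] == roots.get(roots[rid], roots[rid])
    return _make_cluster_set(roots, length_of, params)


def cluster_bruteforce(
    records: Sequence[ProteinRecord], params: ClusterParams = ClusterParams()
) -> ClusterSet:
    """All-pairs greedy set-cover oracle; quadratic, for small inputs only."""
    _check_unique_ids(records)
    length_of = {r.id: r.length for r in records}
    unassigned = sorted(records, key=lambda r: (-r.length, r.id))
    assignment: dict[str, str] = {}
    while unassigned:
        rep = unassigned.pop(0)
        assignment[rep.id] = rep.id
        remaining = []
        for r in unassigned:
            res = align_pair(r, rep, params)
            if passes_thresholds(res, params):
                assignment[r.id] = rep.id
            else:
                remaining.append(r)
        unassigned = remaining
    return _make_cluster_set(assignment, length_of, params)


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    """Two-column (representative_id, member_id) table, one row per member."""
    rows = [
        {"representative_id": c.representative_id, "member_id": m}
        for c in clusters.clusters
        for m in c.member_ids
    ]
    write_tsv_table(rows, path, columns=["representative_id", "member_id"])


def read_clusters_tsv(path: str | Path, params: ClusterParams | None = None) -> ClusterSet:
    rows = read_tsv_table(path)
    by_rep: dict[str, list[str]] = {}
    for row in rows:
        by_rep.setdefault(row["representative_id"], []).append(row["member_id"])
    clusters = [
        Cluster(representative_id=rep, member_ids=members)
        for rep, members in sorted(by_rep.items())
    ]
    return ClusterSet(clusters=clusters, params=params or ClusterParams())
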