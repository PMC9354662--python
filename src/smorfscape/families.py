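"""Three-rule isolation of confident small-protein families from clusters.

Rule 1: only proteins of at most ``max_small_length`` residues are small.
Rule 2: a cluster containing any long member is disqualified outright —
short sequences clustered with long ones are treated as fragments.
Rule 3: a surviving cluster must have at least ``min_members`` members, so
the same small protein must re-occur several times in the sample before it
is believed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .clustering import ClusterSet
from .io import ProteinRecord


@dataclass(frozen=True)
class FamilyParams:
    max_small_length: int = 100
    min_members: int = 4
    #: if True, drop only the short members of mixed clusters instead of the
    #: whole cluster (the permissive reading of rule 2)
    drop_members_only: bool = False

    def __post_init__(self) -> None:
        if self.max_small_length < 1 or self.min_members < 1:
            raise ValueError("FamilyParams fields must be positive")


@dataclass
class SmallProteinFamily:
    family_id: str
    representative: ProteinRecord
    members: list[ProteinRecord]

    @property
    def size(self) -> int:
        """Copy count s(C) of the family, used by quantification."""
        return len(self.members)


def split_by_length(
    records: Sequence[ProteinRecord], max_small_length: int = 100
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (small, long); the boundary itself is small."""
    small = [r for r in records if r.length <= max_small_length]
    long_ = [r for r in records if r.length > max_small_length]
    return small, long_


def call_families(
    clusters: ClusterSet,
    records: Sequence[ProteinRecord],
    params: FamilyParams = FamilyParams(),
) -> list[SmallProteinFamily]:
    """Apply the three rules to a clustering and return families sorted by id.

    By default any long member disqualifies its whole cluster; with
    ``drop_members_only`` the long members alone are discarded and the
    remaining short members are re-tested against ``min_members``.
    """
    by_id = {r.id: r for r in records}
    families = []
    for cluster in clusters.clusters:
        members = [by_id[m] for m in cluster.member_ids]
        longs = [m for m in members if m.length > params.max_small_length]
        if longs:
            if not params.drop_members_only:
                continue
            members = [m for m in members if m.length <= params.max_small_length]
        if len(members) < params.min_members:
            continue
        rep = min(members, key=lambda r: (-r.length, r.id))
        families.append(
            SmallProteinFamily(
                family_id=rep.id, representative=rep, members=members
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def family_summary(families: Sequence[SmallProteinFamily]) -> list[dict]:
    """One row per family: id, copy count, representative length, diversity."""
    return [
        {
            "family_id": f.family_id,
            "size": f.size,
            "representative_length": f.representative.length,
            "n_distinct_sequences": len({m.sequence for m in f.members}),
        }
        for f in families
    ]
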