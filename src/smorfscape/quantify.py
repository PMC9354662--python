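"""Normalized copy-number quantification and the group-comparison screen.

For each sample the copy number of an annotation A is

    c(A) = sum over families with annotation A of s(C) * 1e6 / sum over ALL
           families of s(C)

where s(C) is the family's member count — copies per million small-protein
copies.  The denominator includes unannotated families by default, so a
sample's column sums to 1e6 only when every family received a label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import UNANNOTATED, AnnotationAssignment
from .families import SmallProteinFamily

SCALE = 1_000_000


@dataclass
class GroupComparison:
    annotation: str
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    q_value: float
    rank: int


def copy_number_table(
    assignments: dict[str, Sequence[AnnotationAssignment]],
    families: dict[str, Sequence[SmallProteinFamily]],
    field: str = "EC",
    annotated_denominator: bool = False,
) -> pd.DataFrame:
    """Annotation x sample table of copies-per-million.

    ``assignments`` and ``families`` are keyed by sample id.  The denominator
    is the total copy count of all called families; with
    ``annotated_denominator`` it is restricted to families that received a
    label (a sensitivity option).
    """
    samples = sorted(families)
    columns: dict[str, dict[str, float]] = {}
    for sample in samples:
        fams = families[sample]
        if not fams:
            raise ValueError(f"sample {sample!r} has no called families")
        sizes = {f.family_id: f.size for f in fams}
        label_of: dict[str, str] = {}
        for a in assignments.get(sample, []):
            if a.field != field:
                continue
            if a.family_id not in sizes:
                raise ValueError(
                    f"assignment for unknown family {a.family_id!r} "
                    f"in sample {sample!r}"
                )
            label_of[a.family_id] = a.label
        annotated_total = sum(
            sizes[fid] for fid, lab in label_of.items() if lab != UNANNOTATED
        )
        denominator = annotated_total if annotated_denominator else sum(sizes.values())
        if denominator == 0:
            raise ValueError(f"sample {sample!r}: zero quantification denominator")
        col: dict[str, float] = {}
        for fid, lab in label_of.items():
            if lab == UNANNOTATED:
                continue
            col[lab] = col.get(lab, 0.0) + sizes[fid]
        columns[sample] = {
            lab: total * SCALE / denominator for lab, total in col.items()
        }
    labels = sorted({lab for col in columns.values() for lab in col})
    table = pd.DataFrame(
        {s: [columns[s].get(lab, 0.0) for lab in labels] for s in samples},
        index=labels,
    )
    table.index.name = "annotation"
    return table


def restrict_to_shared(table: pd.DataFrame) -> pd.DataFrame:
    """Keep annotations observed (value > 0) in every sample."""
    if table.shape[1] < 1:
        raise ValueError("restrict_to_shared needs at least one sample")
    shared = table[(table > 0).all(axis=1)]
    if shared.empty:
        warnings.warn("no annotation is shared by all samples")
    return shared


def compare_groups(
    table: pd.DataFrame,
    groups: dict[str, str],
    log1p: bool = False,
) -> list[GroupComparison]:
    """One-way ANOVA per annotation across sample groups, BH-corrected.

    Returns comparisons sorted ascending by raw p (ties broken by
    annotation), with unique ranks.  Caveat: raw-p ranking can surface
    features whose BH-adjusted q exceeds any usual threshold; both numbers
    are always reported so readers see it.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("compare_groups needs at least two groups")
    members = {
        g: [s for s in table.columns if groups.get(s) == g] for g in group_names
    }
    for g, cols in members.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")

    values = np.log1p(table) if log1p else table
    results = []
    for annotation, row in values.iterrows():
        arrays = [row[cols].to_numpy(dtype=float) for cols in members.values()]
        flat = np.concatenate(arrays)
        if np.allclose(flat, flat[0]):
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = stats.f_oneway(*arrays)
            if not np.isfinite(p):
                f_stat, p = float(f_stat), 1.0
        means = {
            g: float(np.mean(row[cols])) for g, cols in members.items()
        }
        results.append((annotation, means, float(f_stat), float(p)))

    pvals = [r[3] for r in results]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    combined = sorted(
        zip(results, qvals), key=lambda rq: (rq[0][3], rq[0][0])
    )
    return [
        GroupComparison(
            annotation=res[0],
            group_means=res[1],
            f_statistic=res[2],
            p_value=res[3],
            q_value=float(q),
            rank=i + 1,
        )
        for i, (res, q) in enumerate(combined)
    ]


def abundance_long_rows(table: pd.DataFrame) -> list[dict]:
    """Long-format view of an abundance table: one row per
    (annotation, sample) with its copies-per-million value."""
    return [
        {"annotation": annotation, "sample_id": sample,
         "copies_per_million": repr(float(table.loc[annotation, sample]))}
        for annotation in table.index
        for sample in table.columns
    ]


def comparison_table(comparisons: Sequence[GroupComparison]) -> list[dict]:
    rows = []
    for c in comparisons:
        row = {"annotation": c.annotation}
        for g, m in sorted(c.group_means.items()):
            row[f"mean_{g}"] = round(m, 6)
        row.update(
            {
                "F": round(c.f_statistic, 6),
                "p": repr(c.p_value),
                "q": repr(c.q_value),
                "rank": c.rank,
            }
        )
        rows.append(row)
    return rows
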