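"""Category-transition analysis between two sample groups.

Given per-triad bias assignments in two groups (consecutive developmental
stages, or a progenitor cell type against its derivative), this module
tallies the square transition table over the seven categories plus the
``not_expressed`` sentinel, computes the consistency fraction (diagonal
share), labels each ordered category pair with a transition type, and
exports Sankey-ready flow tables.

Transition types are defined on the centroid geometry of the 2-simplex:

* ``self``      — no change.
* ``opposite``  — dominant ↔ suppressed of the same subgenome; these are
  the maximally distant centroid pairs (distance √1.5).
* ``adjacent``  — neighbouring categories: any pair involving balanced
  (the balanced centroid sits between all six biased centroids), and
  dominant/suppressed pairs of different subgenomes, which share half of
  their expressed support (e.g. A-dominant and B-suppressed both load on
  subgenome A).
* ``other``     — the remaining pairs: two dominants, or two suppressed,
  which share no directional relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .bias import CATEGORIES, NOT_EXPRESSED, CategoryAssignment

_LABELS = list(CATEGORIES) + [NOT_EXPRESSED]


@dataclass
class TransitionTable:
    """Counts of triads moving between categories across two groups."""

    counts: pd.DataFrame  # index = from-category, columns = to-category
    from_group: str
    to_group: str

    def total(self, include_not_expressed: bool = True) -> int:
        df = self.counts if include_not_expressed else self.counts.loc[
            list(CATEGORIES), list(CATEGORIES)
        ]
        return int(df.to_numpy().sum())


def transition_matrix(
    assign_from: Iterable[CategoryAssignment],
    assign_to: Iterable[CategoryAssignment],
) -> TransitionTable:
    """Tally category changes over the triads shared by two assignment sets.

    Triads that are not expressed in either group are counted in the
    sentinel row/column rather than dropped, so the table total always
    equals the number of shared triads.
    """
    from_map = {a.triad_id: a for a in assign_from}
    to_map = {a.triad_id: a for a in assign_to}
    shared = [t for t in from_map if t in to_map]
    if not shared:
        raise ValueError("no triads shared between the two assignment sets")
    counts = pd.DataFrame(0, index=_LABELS, columns=_LABELS)
    for t in shared:
        counts.at[from_map[t].category, to_map[t].category] += 1
    return TransitionTable(
        counts=counts,
        from_group=from_map[shared[0]].group,
        to_group=to_map[shared[0]].group,
    )


def consistency_fraction(
    table: TransitionTable, include_not_expressed: bool = False
) -> float:
    """Fraction of triads keeping their category: diagonal share of the table."""
    labels = _LABELS if include_not_expressed else list(CATEGORIES)
    sub = table.counts.loc[labels, labels]
    total = sub.to_numpy().sum()
    if total == 0:
        raise ValueError("transition table has no counts over the included categories")
    diag = sum(sub.at[c, c] for c in labels)
    return float(diag) / float(total)


def _parts(category: str) -> tuple[str, str]:
    """Split a category into (subgenome, kind); balanced → ('', 'balanced')."""
    if category == "balanced":
        return "", "balanced"
    sub, kind = category.split(".")
    return sub, kind


def classify_transition_type(from_category: str, to_category: str) -> str:
    """Label an ordered category pair as self / adjacent / opposite / other."""
    for c in (from_category, to_category):
        if c not in CATEGORIES:
            raise ValueError(f"not an assignable category: {c!r}")
    if from_category == to_category:
        return "self"
    fs, fk = _parts(from_category)
    ts, tk = _parts(to_category)
    if fk == "balanced" or tk == "balanced":
        return "adjacent"
    if fs == ts and fk != tk:
        return "opposite"
    if fk != tk:  # dominant vs suppressed of different subgenomes
        return "adjacent"
    return "other"


def transition_type_table() -> pd.DataFrame:
    """The full 7×7 transition-type table, for auditing the convention."""
    return pd.DataFrame(
        [[classify_transition_type(f, t) for t in CATEGORIES] for f in CATEGORIES],
        index=list(CATEGORIES),
        columns=list(CATEGORIES),
    )


def chain_transitions(
    assignments: Sequence[CategoryAssignment], group_order: Sequence[str]
) -> list[TransitionTable]:
    """Pairwise transition tables over consecutive groups in the given order."""
    if len(group_order) < 2:
        raise ValueError("need at least 2 groups for a transition chain")
    by_group: dict[str, list[CategoryAssignment]] = {g: [] for g in group_order}
    for a in assignments:
        if a.group in by_group:
            by_group[a.group].append(a)
    return [
        transition_matrix(by_group[g1], by_group[g2])
        for g1, g2 in zip(group_order[:-1], group_order[1:])
    ]


def sankey_export(table: TransitionTable, path: str | Path) -> None:
    """Write Sankey-ready flows: source_label, target_label, count, type.

    Zero-count flows are omitted; labels are prefixed with the group names
    so chains over several stages concatenate into one diagram.  Flows
    into or out of the ``not_expressed`` sentinel carry type ``NA``.
    """
    rows = []
    for fr in _LABELS:
        for to in _LABELS:
            n = int(table.counts.at[fr, to])
            if n == 0:
                continue
            if fr in CATEGORIES and to in CATEGORIES:
                ttype = classify_transition_type(fr, to)
            else:
                ttype = "NA"
            rows.append(
                (f"{table.from_group}:{fr}", f"{table.to_group}:{to}", n, ttype)
            )
    pd.DataFrame(
        rows, columns=["source_label", "target_label", "count", "transition_type"]
    ).to_csv(path, sep="\t", index=False)


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    """Write the square count matrix with labeled rows and columns."""
    out = table.counts.copy()
    out.index.name = f"{table.from_group}\\{table.to_group}"
    out.to_csv(path, sep="\t")


def read_transition_table(path: str | Path) -> TransitionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    from_group, to_group = str(df.index.name).split("\\")
    df.index.name = None
    return TransitionTable(counts=df.astype(int), from_group=from_group, to_group=to_group)
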