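"""Nearest-centroid classification of homoeolog-triad expression bias.

A triad's expression state is summarized by the vector of relative
contributions ``(a, b, d)`` of its three homoeologs, obtained by dividing
each homoeolog's TPM by the triad total so the components sum to 1.  The
vector lives on the 2-simplex and is compared, by Euclidean distance in the
full three-component space, against seven fixed reference compositions:

* ``balanced``      (1/3, 1/3, 1/3)
* ``A.dominant``    (1, 0, 0)      — likewise B.dominant, D.dominant
* ``A.suppressed``  (0, 1/2, 1/2)  — likewise B.suppressed, D.suppressed

The triad is assigned the category of the nearest centroid.  Dominant
means one subgenome carries essentially all expression; suppressed means
one subgenome contributes little while the other two split evenly.
Triads whose summed expression falls below a floor are flagged
``not_expressed`` and excluded from category proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: The seven assignable bias categories, in canonical order.  This order is
#: also the deterministic tie-break order for exact-tie classifications.
CATEGORIES: tuple[str, ...] = (
    "balanced",
    "A.dominant",
    "B.dominant",
    "D.dominant",
    "A.suppressed",
    "B.suppressed",
    "D.suppressed",
)

#: Sentinel category for triads below the expression floor.
NOT_EXPRESSED = "not_expressed"

BiasCategory = str  # one of CATEGORIES; NOT_EXPRESSED only in assignment records

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SimplexPoint:
    """A point on the 2-simplex: non-negative fractions summing to 1."""

    frac_A: float
    frac_B: float
    frac_D: float

    def __post_init__(self) -> None:
        comps = (self.frac_A, self.frac_B, self.frac_D)
        if not all(math.isfinite(c) for c in comps):
            raise ValueError(f"non-finite simplex component in {comps}")
        if any(c < 0 for c in comps):
            raise ValueError(f"negative simplex component in {comps}")
        if abs(sum(comps) - 1.0) > 1e-6:
            raise ValueError(f"simplex components {comps} do not sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.frac_A, self.frac_B, self.frac_D], dtype=float)


#: Centroid compositions of the seven categories, keyed by category name.
DEFAULT_CENTROIDS: Mapping[str, SimplexPoint] = {
    "balanced": SimplexPoint(1 / 3, 1 / 3, 1 / 3),
    "A.dominant": SimplexPoint(1.0, 0.0, 0.0),
    "B.dominant": SimplexPoint(0.0, 1.0, 0.0),
    "D.dominant": SimplexPoint(0.0, 0.0, 1.0),
    "A.suppressed": SimplexPoint(0.0, 0.5, 0.5),
    "B.suppressed": SimplexPoint(0.5, 0.0, 0.5),
    "D.suppressed": SimplexPoint(0.5, 0.5, 0.0),
}

CentroidSet = Mapping[str, SimplexPoint]


def centroid_array(centroids: CentroidSet = DEFAULT_CENTROIDS) -> tuple[list[str], np.ndarray]:
    """Return category names (canonical order first) and a (k, 3) array."""
    names = [c for c in CATEGORIES if c in centroids]
    names += [c for c in centroids if c not in names]
    arr = np.vstack([centroids[c].as_array() for c in names])
    return names, arr


@dataclass(frozen=True)
class CategoryAssignment:
    """Bias category of one triad in one sample group."""

    triad_id: str
    group: str
    point: SimplexPoint | None  # None for not-expressed triads
    category: str  # a CATEGORIES member, or NOT_EXPRESSED
    distance: float  # NaN for not-expressed triads
    tie: bool = False  # True if ≥2 centroids were exactly equidistant

    def __post_init__(self) -> None:
        if self.category == NOT_EXPRESSED:
            if self.point is not None:
                raise ValueError("not_expressed assignment must have no point")
        elif self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def expressed(self) -> bool:
        return self.category != NOT_EXPRESSED


def summarize_group(matrix: "ExpressionMatrix", group: str) -> pd.Series:
    """Per-gene arithmetic mean of expression over a group's replicates.

    Replicates are averaged on the TPM scale before any triad
    normalization, so each group contributes a single composite sample.
    """
    samples = matrix.samples_in_group(group)
    if not samples:
        raise KeyError(f"unknown group {group!r}")
    return matrix.values[samples].mean(axis=1)


def normalize_triad(
    a: float, b: float, d: float, min_total: float = 0.5
) -> SimplexPoint | None:
    """Scale a triad's (A, B, D) TPM values to unit sum.

    Returns ``None`` if the summed expression is below ``min_total`` TPM,
    marking the triad not expressed (a zero-sum triad cannot be
    normalized, and very low totals give meaningless fractions).
    """
    for name, v in (("a", a), ("b", b), ("d", d)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite expression value {name}={v}")
        if v < 0:
            raise ValueError(f"negative expression value {name}={v}")
    total = a + b + d
    if total < min_total:
        return None
    return SimplexPoint(a / total, b / total, d / total)


def _classify_points(
    points: np.ndarray, centroids: CentroidSet = DEFAULT_CENTROIDS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nearest-centroid assignment.

    Returns (category index into canonical order, distance, tie flag) for
    an (n, 3) array of simplex points.  Ties are broken by the canonical
    category order and flagged.
    """
    names, cent = centroid_array(centroids)
    dists = cdist(points, cent)  # (n, k)
    idx = np.argmin(dists, axis=1)  # argmin takes the first minimum → canonical order
    best = dists[np.arange(len(points)), idx]
    ties = (np.isclose(dists, best[:, None], rtol=0.0, atol=1e-12).sum(axis=1)) > 1
    return idx, best, ties


def classify_triad(
    point: SimplexPoint, centroids: CentroidSet = DEFAULT_CENTROIDS
) -> tuple[str, float]:
    """Assign the bias category whose centroid is nearest to ``point``.

    Distance is Euclidean over the three components.  Exact ties go to the
    earliest category in canonical order.
    """
    names, _ = centroid_array(centroids)
    idx, dist, _tie = _classify_points(point.as_array()[None, :], centroids)
    return names[int(idx[0])], float(dist[0])


def assign_all(
    matrix: "ExpressionMatrix",
    triads: "TriadSet",
    min_total: float = 0.5,
    centroids: CentroidSet = DEFAULT_CENTROIDS,
) -> list[CategoryAssignment]:
    """Classify every triad in every sample group of an expression matrix.

    Per group, replicate TPM values are averaged (:func:`summarize_group`),
    each triad is normalized to unit sum (:func:`normalize_triad`, with
    triads whose total falls below ``min_total`` flagged not expressed) and
    classified by nearest centroid.  Triad genes absent from the matrix are
    treated as zero expression, with a logged warning.
    """
    if len(triads) == 0:
        raise ValueError("empty triad set")
    names, _ = centroid_array(centroids)
    gene_index = {g: i for i, g in enumerate(matrix.values.index)}
    missing = [
        g
        for entry in triads
        for g in (entry.gene_A, entry.gene_B, entry.gene_D)
        if g not in gene_index
    ]
    if missing:
        logger.warning(
            "%d triad gene(s) absent from expression matrix, treated as zero "
            "expression: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            "…" if len(missing) > 5 else "",
        )
    out: list[CategoryAssignment] = []
    for group in matrix.groups():
        means = summarize_group(matrix, group).to_numpy()

        def val(g: str) -> float:
            i = gene_index.get(g)
            return float(means[i]) if i is not None else 0.0

        abd = np.array(
            [[val(e.gene_A), val(e.gene_B), val(e.gene_D)] for e in triads],
            dtype=float,
        )
        totals = abd.sum(axis=1)
        expressed = totals >= min_total
        fracs = np.full_like(abd, np.nan)
        fracs[expressed] = abd[expressed] / totals[expressed, None]
        if expressed.any():
            idx, dist, ties = _classify_points(fracs[expressed], centroids)
        exp_pos = 0
        for i, entry in enumerate(triads):
            if expressed[i]:
                pt = SimplexPoint(*fracs[i])
                out.append(
                    CategoryAssignment(
                        triad_id=entry.triad_id,
                        group=group,
                        point=pt,
                        category=names[int(idx[exp_pos])],
                        distance=float(dist[exp_pos]),
                        tie=bool(ties[exp_pos]),
                    )
                )
                exp_pos += 1
            else:
                out.append(
                    CategoryAssignment(
                        triad_id=entry.triad_id,
                        group=group,
                        point=None,
                        category=NOT_EXPRESSED,
                        distance=float("nan"),
                    )
                )
    return out


def category_proportions(
    assignments: Iterable[CategoryAssignment], group: str
) -> dict[str, float]:
    """Fraction of each bias category among expressed triads of a group.

    Not-expressed triads are excluded from the denominator; use
    :func:`proportions_table` to see their count alongside.
    """
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for a in assignments:
        if a.group != group:
            continue
        if a.expressed:
            counts[a.category] += 1
            n += 1
    if n == 0:
        raise ValueError(f"no expressed triads in group {group!r}")
    return {c: counts[c] / n for c in CATEGORIES}


def proportions_table(assignments: Sequence[CategoryAssignment]) -> pd.DataFrame:
    """Per-group category proportions plus expressed / not-expressed counts.

    Rows follow first appearance order of groups in ``assignments``;
    columns are the seven categories (proportions over expressed triads),
    ``n_expressed`` and ``n_not_expressed``.
    """
    groups: list[str] = []
    for a in assignments:
        if a.group not in groups:
            groups.append(a.group)
    rows = []
    for g in groups:
        props = category_proportions(assignments, g)
        n_exp = sum(1 for a in assignments if a.group == g and a.expressed)
        n_ne = sum(1 for a in assignments if a.group == g and not a.expressed)
        rows.append({**props, "n_expressed": n_exp, "n_not_expressed": n_ne})
    return pd.DataFrame(rows, index=pd.Index(groups, name="group"))


_SQRT3_2 = math.sqrt(3.0) / 2.0


def ternary_coordinates(point: SimplexPoint) -> tuple[float, float]:
    """Cartesian coordinates of a simplex point for ternary plotting.

    Vertices: A at (0, 0), B at (1, 0), D at (1/2, √3/2).
    """
    x = point.frac_B + point.frac_D / 2.0
    y = point.frac_D * _SQRT3_2
    return x, y
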