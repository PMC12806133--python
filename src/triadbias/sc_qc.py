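"""Cell-level quality control, per-cell normalization and pseudo-bulk.

Filters follow the convention of droplet scRNA-seq preprocessing in plant
tissue: cells are excluded when total UMI falls below 500 or exceeds
50,000, detected genes fall below 200 or exceed 10,000, the mitochondrial
read fraction exceeds 1% or the chloroplast fraction exceeds 5%.  All
bounds are strict-violation rules, so a cell sitting exactly on a boundary
is retained.  Retained cells can be log-normalized per cell or aggregated
into per-cell-type pseudo-bulk profiles (summed counts, scaled to counts
per million) for downstream triad-bias classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse

from .io import CellMatrix, ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter thresholds; defaults follow standard wheat spike scRNA-seq QC."""

    umi_min: int = 500
    umi_max: int = 50_000
    genes_min: int = 200
    genes_max: int = 10_000
    mito_max_fraction: float = 0.01
    chloro_max_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not self.genes_min < self.genes_max:
            raise ValueError("genes_min must be < genes_max")
        for f in (self.mito_max_fraction, self.chloro_max_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("organelle fractions must lie in [0, 1]")


#: Rule names in evaluation order.  ``doublet`` is reserved for external
#: doublet-removal tools and never triggered here.
RULES = ("low_umi", "high_umi", "low_genes", "high_genes", "high_mito", "high_chloro")
RESERVED_RULES = ("doublet",)


@dataclass
class QCReport:
    """Per-cell QC metrics and per-rule removal tallies.

    ``per_cell`` is indexed by barcode with columns total_umi,
    genes_detected, mito_fraction, chloro_fraction, kept, failed_rules
    (comma-joined, empty when kept).  ``summary`` counts, per rule, the
    removed cells that failed it; a cell failing several rules appears in
    each of their tallies, so the summary total can exceed the number of
    removed cells.
    """

    per_cell: pd.DataFrame
    summary: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.per_cell["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.per_cell["kept"]).sum())


def apply_cell_filters(
    cells: CellMatrix, thresholds: QCThresholds | None = None
) -> tuple[CellMatrix, QCReport]:
    """Remove cells violating any QC rule; report every failure per cell.

    A cell is retained iff umi_min ≤ UMI ≤ umi_max, genes_min ≤ detected
    genes ≤ genes_max, mito fraction ≤ mito_max_fraction and chloroplast
    fraction ≤ chloro_max_fraction (boundary values retained).
    """
    thr = thresholds or QCThresholds()
    if cells.n_cells == 0:
        raise ValidationError("empty cell matrix")
    counts = cells.counts.copy()
    counts.eliminate_zeros()
    total = np.asarray(counts.sum(axis=1)).ravel()
    genes_detected = counts.getnnz(axis=1)
    mito = np.asarray(counts[:, cells.organelle_mask("mitochondrial")].sum(axis=1)).ravel()
    chloro = np.asarray(counts[:, cells.organelle_mask("chloroplast")].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        chloro_frac = np.where(total > 0, chloro / np.maximum(total, 1), 0.0)

    failed: list[list[str]] = []
    for i in range(cells.n_cells):
        f = []
        if total[i] < thr.umi_min:
            f.append("low_umi")
        if total[i] > thr.umi_max:
            f.append("high_umi")
        if genes_detected[i] < thr.genes_min:
            f.append("low_genes")
        if genes_detected[i] > thr.genes_max:
            f.append("high_genes")
        if mito_frac[i] > thr.mito_max_fraction:
            f.append("high_mito")
        if chloro_frac[i] > thr.chloro_max_fraction:
            f.append("high_chloro")
        failed.append(f)
    kept = np.array([not f for f in failed])

    per_cell = pd.DataFrame(
        {
            "total_umi": total.astype(int),
            "genes_detected": genes_detected.astype(int),
            "mito_fraction": mito_frac,
            "chloro_fraction": chloro_frac,
            "kept": kept,
            "failed_rules": [",".join(f) for f in failed],
        },
        index=pd.Index(cells.barcodes, name="barcode"),
    )
    summary = {
        rule: int(sum(rule in f for f in failed)) for rule in RULES
    }
    report = QCReport(per_cell=per_cell, summary=summary)

    keep_idx = np.flatnonzero(kept)
    kept_barcodes = [cells.barcodes[i] for i in keep_idx]
    labels = None
    if cells.cell_labels is not None:
        labels = {b: cells.cell_labels[b] for b in kept_barcodes if b in cells.cell_labels}
    filtered = CellMatrix(
        counts=cells.counts[keep_idx],
        barcodes=kept_barcodes,
        genes=list(cells.genes),
        gene_flags=dict(cells.gene_flags),
        cell_labels=labels,
    )
    return filtered, report


def log_normalize(cells: CellMatrix, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Per-cell log normalization: ln(1 + count / cell_total × scale_factor).

    Returns a gene-by-cell DataFrame.  Cells with zero total UMI cannot be
    normalized and raise, naming the offending barcode.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    total = np.asarray(cells.counts.sum(axis=1)).ravel()
    zeros = np.flatnonzero(total == 0)
    if zeros.size:
        raise ValidationError(
            f"cell {cells.barcodes[zeros[0]]!r} has zero total UMI"
        )
    scaled = scipy.sparse.diags(scale_factor / total) @ cells.counts
    normed = scaled.copy()
    normed.data = np.log1p(normed.data)
    return pd.DataFrame(
        normed.toarray().T, index=pd.Index(cells.genes, name="gene_id"), columns=cells.barcodes
    )


def pseudo_bulk(
    cells: CellMatrix, labels: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Aggregate cells into per-cell-type expression profiles.

    Raw counts are summed over the member cells of each cell type, then
    scaled to counts per million so every cell-type column sums to 1e6 —
    a bulk-like relative scale comparable to TPM for triad normalization.
    """
    lab = labels if labels is not None else cells.cell_labels
    if lab is None:
        raise ValidationError("no cell labels provided")
    unlabeled = [b for b in cells.barcodes if b not in lab]
    if unlabeled:
        raise ValidationError(f"unlabeled barcode {unlabeled[0]!r}")
    types: list[str] = []
    for b in cells.barcodes:
        if lab[b] not in types:
            types.append(lab[b])
    cols = {}
    for t in types:
        idx = [i for i, b in enumerate(cells.barcodes) if lab[b] == t]
        summed = np.asarray(cells.counts[idx].sum(axis=0)).ravel().astype(float)
        total = summed.sum()
        if total == 0:
            raise ValidationError(f"cell type {t!r} has zero total counts")
        cols[t] = summed / total * 1e6
    values = pd.DataFrame(cols, index=pd.Index(cells.genes, name="gene_id"))
    meta = pd.DataFrame(
        {"group": types, "replicate": ["pseudobulk"] * len(types)},
        index=pd.Index(types, name="sample_id"),
    )
    return ExpressionMatrix(values=values, sample_meta=meta)
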