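"""Readers and writers for the tabular and sparse formats the pipeline uses.

All tabular files are UTF-8, tab-separated with a header row and no
quoting.  Cell matrices follow the CellRanger-style MatrixMarket triple
(``matrix.mtx`` with 1-based coordinates, plus barcode and feature lists),
with organelle membership supplied as a separate two-column flag table
because organellar genes are identified by reference accession, not by a
parseable id pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .bias import CATEGORIES, NOT_EXPRESSED, CategoryAssignment, SimplexPoint


class ValidationError(ValueError):
    """Input parsed but violated a data invariant."""


class FormatError(ValueError):
    """Input did not conform to the expected file format."""


GENE_FLAGS = ("nuclear", "mitochondrial", "chloroplast")


class TriadEntry(NamedTuple):
    triad_id: str
    gene_A: str
    gene_B: str
    gene_D: str


@dataclass
class TriadSet:
    """Homoeolog grouping: one A/B/D gene trio per triad, order preserved."""

    entries: list[TriadEntry]

    def __post_init__(self) -> None:
        self.entries = [TriadEntry(*e) for e in self.entries]
        seen_triads: set[str] = set()
        seen_genes: dict[str, str] = {}
        for e in self.entries:
            if e.triad_id in seen_triads:
                raise ValidationError(f"duplicate triad_id {e.triad_id!r}")
            seen_triads.add(e.triad_id)
            genes = (e.gene_A, e.gene_B, e.gene_D)
            if len(set(genes)) != 3:
                raise ValidationError(
                    f"triad {e.triad_id!r} has non-distinct gene ids {genes}"
                )
            for g in genes:
                if g in seen_genes:
                    raise ValidationError(
                        f"gene {g!r} appears in triads {seen_genes[g]!r} and {e.triad_id!r}"
                    )
                seen_genes[g] = e.triad_id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TriadEntry]:
        return iter(self.entries)

    def all_genes(self) -> list[str]:
        return [g for e in self.entries for g in (e.gene_A, e.gene_B, e.gene_D)]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM-scale values with per-sample group/replicate labels.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``group`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"negative or non-finite value {self.values.iat[i, j]!r} at "
                f"gene {self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} has no metadata")
        for col in ("group", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        if (self.sample_meta["group"].astype(str).str.len() == 0).any():
            raise ValidationError("empty group label in sample metadata")

    def groups(self) -> list[str]:
        """Group labels in first-appearance order over the value columns."""
        out: list[str] = []
        for s in self.values.columns:
            g = str(self.sample_meta.at[s, "group"])
            if g not in out:
                out.append(g)
        return out

    def samples_in_group(self, group: str) -> list[str]:
        return [
            s
            for s in self.values.columns
            if str(self.sample_meta.at[s, "group"]) == group
        ]


@dataclass
class CellMatrix:
    """Sparse barcode-by-gene UMI counts with organelle flags.

    ``counts``: CSR matrix, rows = barcodes, columns = genes.
    ``gene_flags``: per-gene membership in {nuclear, mitochondrial,
    chloroplast}.  ``cell_labels`` optionally maps barcodes to cell types.
    """

    counts: scipy.sparse.csr_matrix
    barcodes: list[str]
    genes: list[str]
    gene_flags: Mapping[str, str]
    cell_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes × {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        for g in self.genes:
            flag = self.gene_flags.get(g)
            if flag is None:
                raise ValidationError(f"gene {g!r} missing from flags table")
            if flag not in GENE_FLAGS:
                raise ValidationError(f"gene {g!r} has unknown flag {flag!r}")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def organelle_mask(self, flag: str) -> np.ndarray:
        return np.array([self.gene_flags[g] == flag for g in self.genes])


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def read_triads(path: str | Path) -> TriadSet:
    """Read a triad definition table (triad_id, gene_A, gene_B, gene_D)."""
    df = _read_tsv(path, ["triad_id", "gene_A", "gene_B", "gene_D"])
    entries = [
        TriadEntry(r.triad_id, r.gene_A, r.gene_B, r.gene_D)
        for r in df.itertuples(index=False)
    ]
    return TriadSet(entries)


def write_triads(triads: TriadSet, path: str | Path) -> None:
    df = pd.DataFrame(triads.entries, columns=["triad_id", "gene_A", "gene_B", "gene_D"])
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV plus its sample metadata table.

    The expression table's first column holds gene ids; remaining columns
    are samples.  Metadata columns: sample_id, group, replicate.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = _read_tsv(meta_path, ["sample_id", "group", "replicate"])
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=df, sample_meta=meta)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_cell_matrix(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    flags_path: str | Path,
    labels_path: str | Path | None = None,
) -> CellMatrix:
    """Read a MatrixMarket cell-by-gene triple plus an organelle-flag table.

    The .mtx file uses 1-based coordinates with rows = barcodes and
    columns = genes; entries absent from the file are zero.
    """
    barcodes = Path(barcodes_path).read_text().split()
    genes = Path(features_path).read_text().split()
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape[0] > len(barcodes) or mat.shape[1] > len(genes):
        raise FormatError(
            f"{matrix_path}: matrix dimensions {mat.shape} exceed "
            f"{len(barcodes)} barcodes × {len(genes)} genes"
        )
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer count present")
    counts = scipy.sparse.csr_matrix(
        (mat.data, (mat.row, mat.col)), shape=(len(barcodes), len(genes))
    )
    flags_df = _read_tsv(flags_path, ["gene_id", "flag"])
    flags = dict(zip(flags_df["gene_id"], flags_df["flag"]))
    labels = None
    if labels_path is not None:
        lab_df = _read_tsv(labels_path, ["barcode", "cell_type"])
        labels = dict(zip(lab_df["barcode"], lab_df["cell_type"]))
    return CellMatrix(counts, barcodes, genes, flags, labels)


def write_cell_matrix(cells: CellMatrix, out_dir: str | Path) -> None:
    """Write the MatrixMarket triple (+ flags, + labels if present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), scipy.sparse.coo_matrix(cells.counts))
    (out / "barcodes.tsv").write_text("\n".join(cells.barcodes) + "\n")
    (out / "features.tsv").write_text("\n".join(cells.genes) + "\n")
    pd.DataFrame(
        {"gene_id": cells.genes, "flag": [cells.gene_flags[g] for g in cells.genes]}
    ).to_csv(out / "flags.tsv", sep="\t", index=False)
    if cells.cell_labels is not None:
        pd.DataFrame(
            {
                "barcode": cells.barcodes,
                "cell_type": [cells.cell_labels.get(b, "") for b in cells.barcodes],
            }
        ).to_csv(out / "labels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# assignment tables

ASSIGNMENT_COLUMNS = (
    "triad_id",
    "group",
    "frac_A",
    "frac_B",
    "frac_D",
    "category",
    "distance",
)


def write_assignments(
    assignments: Sequence[CategoryAssignment], path: str | Path
) -> None:
    """Serialize assignments as TSV, sorted by (triad_id, group).

    Fractions and distances are printed with 6 decimals; not-expressed
    triads get ``NA`` in the numeric columns.
    """
    rows = []
    for a in sorted(assignments, key=lambda a: (a.triad_id, a.group)):
        if a.expressed:
            assert a.point is not None
            rows.append(
                (
                    a.triad_id,
                    a.group,
                    f"{a.point.frac_A:.6f}",
                    f"{a.point.frac_B:.6f}",
                    f"{a.point.frac_D:.6f}",
                    a.category,
                    f"{a.distance:.6f}",
                )
            )
        else:
            rows.append((a.triad_id, a.group, "NA", "NA", "NA", NOT_EXPRESSED, "NA"))
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[CategoryAssignment]:
    """Read an assignment table written by :func:`write_assignments`."""
    df = _read_tsv(path, ASSIGNMENT_COLUMNS)
    out: list[CategoryAssignment] = []
    for r in df.itertuples(index=False):
        if r.category == NOT_EXPRESSED:
            out.append(
                CategoryAssignment(r.triad_id, r.group, None, NOT_EXPRESSED, float("nan"))
            )
        else:
            fracs = np.array([float(r.frac_A), float(r.frac_B), float(r.frac_D)])
            fracs = fracs / fracs.sum()  # undo 6-decimal rounding drift
            out.append(
                CategoryAssignment(
                    r.triad_id,
                    r.group,
                    SimplexPoint(*fracs),
                    r.category,
                    float(r.distance),
                )
            )
    return out
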