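"""Expression-matrix and gene-list IO.

Expression matrices are tab-separated text, genes as rows and samples
as columns by default (the common compendium distribution layout), with
gene IDs in the first column and sample IDs in the header.  Regulator
panels are plain text, one gene ID per line.  All writes are atomic
(write to a temporary file, then rename) so interrupted runs never
leave partial outputs.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "split_regulators",
    "variance_filter_targets",
    "write_coefficients",
    "atomic_write_text",
]


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a regulator partition."""

    matrix: np.ndarray  # genes x samples
    gene_ids: list
    sample_ids: list
    regulator_flags: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene IDs are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs are not unique")
        if self.regulator_flags is not None:
            self.regulator_flags = np.asarray(self.regulator_flags, dtype=bool)
            if self.regulator_flags.size != len(self.gene_ids):
                raise ValueError("regulator flag vector length must equal gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)


def read_expression(path, orientation: str = "genes_by_samples") -> ExpressionDataset:
    """Parse a TSV expression matrix.

    Duplicated IDs, non-numeric cells, missing values and ragged rows
    are each rejected with the offending row/column named.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    col_ids = [c.strip() for c in header[1:]]
    n_cols = len(col_ids)
    if n_cols == 0:
        raise ValueError(f"{path}: header has no sample columns")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols + 1:
            raise ValueError(
                f"{path}: line {i} has {len(parts) - 1} values, expected {n_cols}"
            )
        rid = parts[0].strip()
        vals = []
        for j, cell in enumerate(parts[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise ValueError(
                    f"{path}: missing value at row {rid!r}, column {col_ids[j]!r}"
                )
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {rid!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value at row {rid!r}, column {col_ids[j]!r}"
                )
            vals.append(v)
        row_ids.append(rid)
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dup = _first_duplicate(row_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicated row ID {dup!r}")
    dup = _first_duplicate(col_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicated column ID {dup!r}")
    M = np.asarray(rows, dtype=float)
    if orientation == "genes_by_samples":
        return ExpressionDataset(matrix=M, gene_ids=row_ids, sample_ids=col_ids)
    return ExpressionDataset(matrix=M.T, gene_ids=col_ids, sample_ids=row_ids)


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def write_expression(ds: ExpressionDataset, path, float_format: str = "%.10g") -> None:
    """Write the dataset as a genes-by-samples TSV (atomic)."""
    lines = ["\t".join(["gene"] + list(ds.sample_ids))]
    for gid, row in zip(ds.gene_ids, ds.matrix):
        lines.append("\t".join([str(gid)] + [float_format % v for v in row]))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gene_list(path) -> list:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    if not out:
        raise ValueError(f"{path}: gene list is empty")
    return out


def write_gene_list(ids, path) -> None:
    atomic_write_text(path, "\n".join(str(i) for i in ids) + "\n")


def split_regulators(ds: ExpressionDataset, regulators):
    """Partition genes into regulators (X) and targets (Y).

    ``regulators`` is a path to a gene list or an iterable of IDs.
    Returns (X, Y, regulator_ids, target_ids) with samples as rows; X
    columns follow the regulator-list order, Y columns follow dataset
    order.
    """
    if isinstance(regulators, (str, os.PathLike)):
        regulators = read_gene_list(regulators)
    reg_ids = list(regulators)
    index = {g: i for i, g in enumerate(ds.gene_ids)}
    unknown = [g for g in reg_ids if g not in index]
    if unknown:
        raise ValueError(f"regulators absent from the dataset: {', '.join(map(str, unknown))}")
    reg_set = set(reg_ids)
    target_ids = [g for g in ds.gene_ids if g not in reg_set]
    if not reg_ids:
        raise ValueError("no regulators listed")
    if not target_ids:
        raise ValueError("regulator list covers every gene; no targets remain")
    X = ds.matrix[[index[g] for g in reg_ids], :].T
    Y = ds.matrix[[index[g] for g in target_ids], :].T
    return X, Y, reg_ids, target_ids


def variance_filter_targets(
    ds: ExpressionDataset, regulators, top_k: int
) -> ExpressionDataset:
    """Keep all regulators plus the top_k highest-variance targets.

    Variance is across samples, computed on the stored (pre-
    standardization) values; ties break lexically on gene ID for
    determinism.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if isinstance(regulators, (str, os.PathLike)):
        regulators = read_gene_list(regulators)
    reg_set = set(regulators)
    targets = [g for g in ds.gene_ids if g not in reg_set]
    if top_k > len(targets):
        raise ValueError(f"top_k={top_k} exceeds the {len(targets)} available targets")
    index = {g: i for i, g in enumerate(ds.gene_ids)}
    var = {g: float(np.var(ds.matrix[index[g]])) for g in targets}
    kept = set(sorted(targets, key=lambda g: (-var[g], str(g)))[:top_k])
    keep_rows = [i for i, g in enumerate(ds.gene_ids) if g in reg_set or g in kept]
    return ExpressionDataset(
        matrix=ds.matrix[keep_rows, :],
        gene_ids=[ds.gene_ids[i] for i in keep_rows],
        sample_ids=list(ds.sample_ids),
        regulator_flags=np.array([ds.gene_ids[i] in reg_set for i in keep_rows]),
        standardized=ds.standardized,
    )


def write_coefficients(W, row_ids, col_ids, path, float_format: str = "%.10g") -> None:
    """Coefficient matrix as TSV with row and column labels (atomic)."""
    W = np.asarray(W, dtype=float)
    if W.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"coefficients shape {W.shape} does not match {len(row_ids)} x {len(col_ids)} labels"
        )
    lines = ["\t".join(["id"] + [str(c) for c in col_ids])]
    for rid, row in zip(row_ids, W):
        lines.append("\t".join([str(rid)] + [float_format % v for v in row]))
    atomic_write_text(path, "\n".join(lines) + "\n")
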