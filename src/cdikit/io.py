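"""Readers and writers for count matrices, label sets, and result tables.

Count matrices are genes x cells throughout: rows are genes, columns are
cells.  Two on-disk layouts are supported, Matrix Market coordinate triplets
with companion one-ID-per-line gene/cell files, and dense delimited text.
Matrix Market indices are 1-based on disk (per the standard) and converted
to 0-based exactly once at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "LabelSet",
    "read_count_matrix",
    "read_label_sets",
    "read_batches",
    "write_report",
    "read_report",
]

#: stable column order for CDI report tables
REPORT_COLUMNS = ["label_set", "K", "neg2loglik", "df", "CDI_AIC", "CDI_BIC"]


class FormatError(ValueError):
    """Malformed file contents (non-integer entries, negative counts, ...)."""


class StructuralError(ValueError):
    """Shape or ID bookkeeping mismatch between companion inputs."""


@dataclass
class CountMatrix:
    """A genes x cells UMI count matrix with IDs and optional batch labels.

    Parameters
    ----------
    values
        Integer array of shape ``(n_genes, n_cells)`` with non-negative
        entries.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    batch
        Optional per-cell batch label (length ``n_cells``).  Defines the
        batch index sets used by multi-batch feature selection and the
        batch-effect likelihood-ratio test.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise StructuralError("count matrix must be two-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = np.asarray(self.values)
            rounded = np.rint(as_int)
            if not np.all(np.isfinite(as_int)) or np.any(rounded != as_int):
                bad = np.argwhere(~np.isfinite(as_int) | (np.rint(as_int) != as_int))
                g, c = bad[0]
                raise FormatError(
                    f"non-integer count at gene index {g}, cell index {c}: "
                    f"{self.values[g, c]!r}"
                )
            self.values = rounded.astype(np.int64)
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative count at gene index {g}, cell index {c}: "
                f"{self.values[g, c]}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise StructuralError(
                f"{len(self.gene_ids)} gene IDs for {self.values.shape[0]} rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise StructuralError(
                f"{len(self.cell_ids)} cell IDs for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise StructuralError("duplicate gene IDs")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise StructuralError("duplicate cell IDs")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.shape != (self.values.shape[1],):
                raise StructuralError(
                    "batch vector length does not match the cell count"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def batch_levels(self) -> list:
        """Distinct batch labels in first-occurrence order (empty if no batch)."""
        if self.batch is None:
            return []
        return list(pd.unique(self.batch))

    def cells_in_batch(self, level) -> np.ndarray:
        """0-based column indices of the cells in batch ``level``."""
        if self.batch is None:
            raise StructuralError("count matrix has no batch labels")
        return np.flatnonzero(self.batch == level)

    def subset_genes(self, genes) -> "CountMatrix":
        """Restrict to ``genes`` (IDs or integer indices), preserving order."""
        genes = list(genes)
        if genes and isinstance(genes[0], (int, np.integer)):
            idx = np.asarray(genes, dtype=int)
        else:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            missing = [g for g in genes if g not in lookup]
            if missing:
                raise StructuralError(f"unknown gene IDs: {missing[:5]}")
            idx = np.asarray([lookup[g] for g in genes], dtype=int)
        return CountMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
            None if self.batch is None else self.batch.copy(),
        )

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx, dtype=int)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
            None if self.batch is None else self.batch[idx],
        )


@dataclass
class LabelSet:
    """A per-cell cluster assignment with labels recoded to ``1..K``.

    ``from_raw`` recodes arbitrary cluster names to contiguous integers in
    first-occurrence order, so downstream code may assume every cluster id
    in ``{1..K}`` occurs at least once.
    """

    labels: np.ndarray
    name: str = "labels"
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise StructuralError(f"label set {self.name!r} is empty or not 1-D")
        present = np.unique(self.labels)
        self.K = int(present.size)
        if present[0] != 1 or present[-1] != self.K:
            raise StructuralError(
                f"label set {self.name!r} is not coded 1..K; use LabelSet.from_raw"
            )

    @classmethod
    def from_raw(cls, values, name: str = "labels") -> "LabelSet":
        values = np.asarray(values)
        if values.ndim != 1 or values.size == 0:
            raise StructuralError(f"label set {name!r} is empty or not 1-D")
        codes = pd.Series(values).astype(str)
        order = {v: i + 1 for i, v in enumerate(pd.unique(codes))}
        return cls(codes.map(order).to_numpy(), name=name)

    def cluster_cells(self, k: int) -> np.ndarray:
        """0-based indices of the cells assigned to cluster ``k`` (1-based)."""
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> np.ndarray:
        """Cluster sizes ``N_k`` for k = 1..K."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise StructuralError(f"empty ID file: {path}")
    return ids


def read_count_matrix(
    path,
    format: str = "auto",
    genes=None,
    cells=None,
    cells_as_rows: bool = False,
    batch=None,
) -> CountMatrix:
    """Read a UMI count matrix from disk.

    Parameters
    ----------
    path
        Matrix file.  ``.mtx`` files are Matrix Market coordinate triplets
        and require companion ``genes``/``cells`` ID files (defaulting to
        ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to the matrix);
        anything else is dense delimited text (whitespace, tab, or comma).
    cells_as_rows
        Declare that the file stores cells in rows; the matrix is transposed
        to the genes x cells orientation after reading.
    batch
        Optional path to a one-label-per-line batch file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "matrix-market-triplet" if path.suffix == ".mtx" else "dense-delimited"

    if format == "matrix-market-triplet":
        genes = Path(genes) if genes else path.with_suffix("").with_suffix(".genes.txt")
        cells = Path(cells) if cells else path.with_suffix("").with_suffix(".cells.txt")
        for companion in (genes, cells):
            if not companion.exists():
                raise FileNotFoundError(f"companion ID file not found: {companion}")
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids, cell_ids = _read_id_file(genes), _read_id_file(cells)
    elif format == "dense-delimited":
        text = path.read_text()
        delim = "," if ("," in text.splitlines()[0]) else None
        try:
            values = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"could not parse dense matrix {path}: {exc}") from exc
        gene_ids = [f"gene{i + 1}" for i in range(values.shape[0])]
        cell_ids = [f"cell{j + 1}" for j in range(values.shape[1])]
        if genes:
            gene_ids = _read_id_file(Path(genes))
        if cells:
            cell_ids = _read_id_file(Path(cells))
    else:
        raise ValueError(f"unknown format {format!r}")

    if cells_as_rows:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids

    batch_vec = None
    if batch is not None:
        batch_vec = np.asarray(_read_id_file(Path(batch)))
    return CountMatrix(values, gene_ids, cell_ids, batch_vec)


def write_count_matrix(counts: CountMatrix, prefix) -> dict:
    """Write ``<prefix>.mtx`` plus gene/cell ID files; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_suffix(".mtx"),
        "genes": prefix.with_suffix(".genes.txt"),
        "cells": prefix.with_suffix(".cells.txt"),
    }
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.coo_matrix(counts.values))
    paths["genes"].write_text("".join(g + "\n" for g in counts.gene_ids))
    paths["cells"].write_text("".join(c + "\n" for c in counts.cell_ids))
    if counts.batch is not None:
        paths["batch"] = prefix.with_suffix(".batch.txt")
        paths["batch"].write_text("".join(str(b) + "\n" for b in counts.batch))
    return paths


def read_label_sets(path, n_cells: int | None = None) -> list[LabelSet]:
    """Read candidate label sets from a delimited file.

    One column per candidate, one row per cell, with a header row of
    label-set names.  Cluster names are recoded to ``1..K`` in
    first-occurrence order.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python", comment="#", dtype=str)
    if df.shape[0] == 0:
        raise StructuralError(f"no label rows in {path}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise StructuralError(f"column {col!r} in {path} has missing entries")
    if n_cells is not None and df.shape[0] != n_cells:
        raise StructuralError(
            f"{path} has {df.shape[0]} rows but the count matrix has {n_cells} cells"
        )
    return [LabelSet.from_raw(df[col].to_numpy(), name=str(col)) for col in df.columns]


def read_batches(path) -> np.ndarray:
    """Read a one-label-per-line per-cell batch vector."""
    return np.asarray(_read_id_file(Path(path)))


def write_report(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a result table as TSV with full float precision.

    Leading ``#`` comment lines carry provenance metadata; a JSON sidecar
    ``<path>.json`` holds the same metadata machine-readably.  The written
    file round-trips losslessly through :func:`read_report`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    if metadata:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2, default=str) + "\n"
        )


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
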