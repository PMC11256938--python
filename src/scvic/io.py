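"""Readers and writers for standard count-matrix formats.

Canonical in-memory orientation is cells-as-rows.  Matrix Market files are
coordinate integer; 10x-style triplet directories (matrix.mtx +
features/genes.tsv + barcodes.tsv) are stored genes-by-cells on disk and
transposed on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import CountDataset


def _validate_counts(mat: np.ndarray, source: str) -> np.ndarray:
    bad_neg = np.argwhere(mat < 0)
    if len(bad_neg):
        i, j = bad_neg[0]
        raise ValueError(f"{source}: negative entry at row {i + 1}, column {j + 1}")
    if not np.allclose(mat, np.round(mat)):
        i, j = np.argwhere(~np.isclose(mat, np.round(mat)))[0]
        raise ValueError(f"{source}: fractional entry at row {i + 1}, column {j + 1}")
    return mat.astype(np.int64)


def _read_lines(path) -> np.ndarray:
    with open(path) as fh:
        return np.array([line.rstrip("\n").split("\t")[0] for line in fh if line.strip()])


def read_counts(
    path,
    fmt: str = "mtx",
    transpose: bool = False,
    batch: np.ndarray | None = None,
) -> CountDataset:
    """Load a count matrix as a :class:`CountDataset`.

    ``fmt`` is one of ``"mtx"`` (sibling ``<stem>_genes.tsv`` /
    ``<stem>_barcodes.tsv`` name files are picked up when present),
    ``"csv"`` (cells x genes with header and index), or ``"10x-dir"``
    (triplet directory, transposed to cells-as-rows automatically).
    ``transpose`` flips the on-disk orientation for mtx/csv.
    """
    path = str(path)
    gene_names = cell_names = None
    if fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=np.float64)
        stem = path[:-4] if path.endswith(".mtx") else path
        if os.path.exists(stem + "_genes.tsv"):
            gene_names = _read_lines(stem + "_genes.tsv")
        if os.path.exists(stem + "_barcodes.tsv"):
            cell_names = _read_lines(stem + "_barcodes.tsv")
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=np.float64)
        cell_names = df.index.to_numpy(dtype=str)
        gene_names = df.columns.to_numpy(dtype=str)
    elif fmt == "10x-dir":
        mtx = os.path.join(path, "matrix.mtx")
        mat = spio.mmread(mtx)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=np.float64).T  # genes x cells on disk
        for cand in ("features.tsv", "genes.tsv"):
            p = os.path.join(path, cand)
            if os.path.exists(p):
                gene_names = _read_lines(p)
                break
        bc = os.path.join(path, "barcodes.tsv")
        if os.path.exists(bc):
            cell_names = _read_lines(bc)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if transpose:
        mat = mat.T
        gene_names, cell_names = cell_names, gene_names
    mat = _validate_counts(mat, path)
    return CountDataset(
        counts=mat, batch=batch, gene_names=gene_names, cell_names=cell_names
    )


def write_counts(dataset: CountDataset, path, fmt: str = "mtx") -> None:
    """Write counts (cells-as-rows) plus name/label sidecar files."""
    path = str(path)
    if fmt == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        spio.mmwrite(
            stem + ".mtx", sparse.coo_matrix(dataset.counts), field="integer"
        )
        np.savetxt(stem + "_genes.tsv", dataset.gene_names, fmt="%s")
        np.savetxt(stem + "_barcodes.tsv", dataset.cell_names, fmt="%s")
    elif fmt == "csv":
        pd.DataFrame(
            dataset.counts, index=dataset.cell_names, columns=dataset.gene_names
        ).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_tenx_dir(dataset: CountDataset, outdir) -> None:
    """Write a 10x-style triplet directory (genes x cells on disk)."""
    os.makedirs(outdir, exist_ok=True)
    spio.mmwrite(
        os.path.join(outdir, "matrix.mtx"),
        sparse.coo_matrix(dataset.counts.T),
        field="integer",
    )
    np.savetxt(os.path.join(outdir, "genes.tsv"), dataset.gene_names, fmt="%s")
    np.savetxt(os.path.join(outdir, "barcodes.tsv"), dataset.cell_names, fmt="%s")


def read_label_tsv(path) -> np.ndarray:
    """One label per cell; either a single column or (cell, label) pairs."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                rows.append(parts[-1])
    return np.array(rows)


def write_label_tsv(path, cell_names, labels) -> None:
    with open(path, "w") as fh:
        for name, lab in zip(cell_names, labels):
            fh.write(f"{name}\t{lab}\n")


def write_latent_csv(path, cell_names, latent: np.ndarray) -> None:
    cols = [f"z{i}" for i in range(latent.shape[1])]
    pd.DataFrame(latent, index=np.asarray(cell_names), columns=cols).to_csv(path)


def read_latent_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=np.float64)
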