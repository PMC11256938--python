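"""Cell-by-gene count container.

Counts are kept dense (int64) with cells as rows.  Batch annotations are
categorical per cell; a single implicit batch is assumed when none are
given.  Genes observed in no cell are dropped at construction time because
their dispersion is not identifiable under the negative-binomial
observation model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CountDataset:
    """Non-negative integer counts for N cells x G genes.

    Parameters
    ----------
    counts
        ``(N, G)`` matrix of raw counts; must be integer-valued and >= 0.
    batch
        Per-cell batch labels (any hashable scalars).  Defaults to a single
        batch ``"batch0"``.
    gene_names, cell_names
        Optional identifiers; synthesized (``g0..``, ``cell0..``) if absent.
    true_labels
        Optional ground-truth group labels (simulations).
    """

    counts: np.ndarray
    batch: np.ndarray | None = None
    gene_names: np.ndarray | None = None
    cell_names: np.ndarray | None = None
    true_labels: np.ndarray | None = None
    drop_zero_genes: bool = True
    batch_categories: np.ndarray = field(init=False)
    batch_codes: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at cell {i}, gene {j}")
        if not np.allclose(counts, np.round(counts)):
            i, j = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
            raise ValueError(f"non-integer count at cell {i}, gene {j}")
        counts = counts.astype(np.int64)

        n, g = counts.shape
        if self.gene_names is None:
            self.gene_names = np.array([f"g{i}" for i in range(g)])
        else:
            self.gene_names = np.asarray(self.gene_names)
        if self.cell_names is None:
            self.cell_names = np.array([f"cell{i}" for i in range(n)])
        else:
            self.cell_names = np.asarray(self.cell_names)

        if self.drop_zero_genes:
            keep = counts.sum(axis=0) > 0
            n_dropped = int((~keep).sum())
            if n_dropped:
                logger.info("dropping %d all-zero genes", n_dropped)
                counts = counts[:, keep]
                self.gene_names = self.gene_names[keep]
        self.counts = counts

        if self.batch is None:
            self.batch = np.array(["batch0"] * n)
        else:
            self.batch = np.asarray(self.batch)
            if len(self.batch) != n:
                raise ValueError("batch length does not match number of cells")
        cats, codes = np.unique(self.batch, return_inverse=True)
        self.batch_categories = cats
        self.batch_codes = codes.astype(np.int64)

        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)
            if len(self.true_labels) != n:
                raise ValueError("true_labels length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_categories)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def batch_onehot(self) -> np.ndarray:
        out = np.zeros((self.n_cells, self.n_batches))
        out[np.arange(self.n_cells), self.batch_codes] = 1.0
        return out

    def subset(self, idx: np.ndarray) -> "CountDataset":
        """Row (cell) subset; keeps gene set fixed (no re-filtering)."""
        return CountDataset(
            counts=self.counts[idx],
            batch=self.batch[idx],
            gene_names=self.gene_names,
            cell_names=self.cell_names[idx],
            true_labels=None if self.true_labels is None else self.true_labels[idx],
            drop_zero_genes=False,
        )

    def without_batch(self) -> "CountDataset":
        """Copy with batch annotation erased (single implicit batch)."""
        return CountDataset(
            counts=self.counts,
            batch=None,
            gene_names=self.gene_names,
            cell_names=self.cell_names,
            true_labels=self.true_labels,
            drop_zero_genes=False,
        )
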