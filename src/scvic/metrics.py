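"""Evaluation metrics: ARI, NMI, and the KNN-region KL divergence of batch
mixing.

ARI and NMI are the standard chance-corrected pair-counting and
information-theoretic partition agreement measures (NMI normalized by the
larger of the two partition entropies).  The batch-mixing score averages,
over randomly chosen KNN regions of the latent space, the KL divergence of
the region's batch composition against the global composition; lower means
better mixing.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


def _check_pair(u, v):
    u = np.asarray(u)
    v = np.asarray(v)
    if u.ndim != 1 or v.ndim != 1 or len(u) != len(v):
        raise ValueError("partitions must be 1-D and of equal length")
    if len(u) == 0:
        raise ValueError("partitions must be non-empty")
    return u, v


def ari(u, v) -> float:
    """Adjusted Rand index between two partitions, in [-1, 1]."""
    u, v = _check_pair(u, v)
    return float(adjusted_rand_score(u, v))


def nmi(u, v) -> float:
    """Normalized mutual information I(U,V)/max(H(U), H(V)), in [0, 1].

    Two single-cluster partitions are identical up to relabeling; the
    degenerate 0/0 is defined as 1 (and logged).
    """
    u, v = _check_pair(u, v)
    if len(np.unique(u)) == 1 and len(np.unique(v)) == 1:
        logger.info("both partitions are single-cluster; NMI defined as 1")
        return 1.0
    return float(normalized_mutual_info_score(u, v, average_method="max"))


def batch_mixing_kl(
    latent: np.ndarray,
    batch: np.ndarray,
    k: int = 50,
    n_regions: int = 50,
    n_iterations: int = 100,
    seed: int = 0,
) -> float:
    """Average regional KL divergence of batch composition.

    Each iteration samples ``n_regions`` query cells; each query's region
    is its ``k`` nearest latent-space neighbors (the query itself is
    excluded).  The region's batch proportions ``q_b`` are compared with
    the global proportions ``p_b`` via ``sum_b q_b log(q_b / p_b)``
    (``0 log 0 = 0``); regions are averaged, then iterations.
    """
    latent = np.asarray(latent, dtype=np.float64)
    batch = np.asarray(batch)
    n = latent.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2 (a region needs at least 2 neighbors)")
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    cats, codes = np.unique(batch, return_inverse=True)
    n_b = len(cats)
    if n_b < 2:
        raise ValueError("batch mixing requires at least 2 batches")
    p = np.bincount(codes, minlength=n_b) / n

    nn = NearestNeighbors(n_neighbors=k + 1).fit(latent)
    _, idx = nn.kneighbors(latent)
    idx = idx[:, 1:]  # exclude the query cell itself
    neighbor_codes = codes[idx]  # (n, k)

    rng = np.random.default_rng(seed)
    n_regions = min(n_regions, n)
    iter_means = np.empty(n_iterations)
    for it in range(n_iterations):
        queries = rng.choice(n, size=n_regions, replace=False)
        region_kl = np.empty(n_regions)
        for r, q_cell in enumerate(queries):
            counts = np.bincount(neighbor_codes[q_cell], minlength=n_b)
            q = counts / k
            pos = q > 0
            region_kl[r] = float(np.sum(q[pos] * np.log(q[pos] / p[pos])))
        iter_means[it] = region_kl.mean()
    return float(iter_means.mean())
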