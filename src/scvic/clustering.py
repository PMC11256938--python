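"""Cluster assignment from a fitted model.

Two routes: the built-in maximum-responsibility rule (each cell goes to the
mixture component with the highest posterior membership at its posterior
mean), and Louvain community detection on a KNN graph over the
deterministic encodings (the "-Louvain" variant).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core import CountDataset, responsibilities
from .inference import ModelState, encode

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    method: str
    responsibilities: np.ndarray | None = None
    graph_params: dict | None = None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _canonicalize(raw: np.ndarray) -> np.ndarray:
    """Relabel to consecutive 0..K-1 in order of first appearance."""
    out = np.empty(len(raw), dtype=np.int64)
    mapping: dict = {}
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def assign_builtin(state: ModelState, dataset: CountDataset) -> ClusteringResult:
    """argmax_c q(c | mu_z) per cell; ties go to the lowest component index."""
    mu_z = encode(state, dataset).mu_z
    resp = responsibilities(mu_z, state.gmm).q_c_z
    raw = np.argmax(resp, axis=1)  # argmax takes the first maximum
    n_ties = int(np.sum((resp == resp.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("%d cells had tied responsibilities; lowest index chosen", n_ties)
    return ClusteringResult(
        labels=_canonicalize(raw), method="builtin", responsibilities=resp
    )


def knn_graph(
    embedding: np.ndarray, n_neighbors: int, weighted: bool = True
) -> igraph.Graph:
    """Symmetrized KNN graph; edges weighted by shared-neighbor (Jaccard)
    connectivity of the endpoint neighborhoods, or unweighted on request."""
    n = embedding.shape[0]
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    idx = idx[:, 1:]  # drop self
    neigh_sets = [set(row) for row in idx]
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in idx[i]:
            key = (min(i, int(j)), max(i, int(j)))
            if key in edges:
                continue
            if weighted:
                a, b = neigh_sets[key[0]], neigh_sets[key[1]]
                inter = len(a & b)
                w = inter / (len(a | b))
                edges[key] = max(w, 1e-6)
            else:
                edges[key] = 1.0
    g = igraph.Graph(n=n, edges=list(edges.keys()))
    g.es["weight"] = list(edges.values())
    return g


def assign_louvain(
    state: ModelState,
    dataset: CountDataset,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    weighted: bool = True,
) -> ClusteringResult:
    """Louvain modularity communities on the KNN graph of the encodings."""
    mu_z = encode(state, dataset).mu_z
    labels = louvain_labels(mu_z, n_neighbors, resolution, seed, weighted)
    return ClusteringResult(
        labels=labels,
        method="louvain",
        graph_params={
            "n_neighbors": n_neighbors,
            "resolution": resolution,
            "seed": seed,
            "weighted": weighted,
        },
    )


def louvain_labels(
    embedding: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    weighted: bool = True,
) -> np.ndarray:
    g = knn_graph(embedding, n_neighbors, weighted=weighted)
    igraph.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return _canonicalize(np.asarray(part.membership))


def write_labels(path, cell_names: np.ndarray, labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        for name, lab in zip(cell_names, labels):
            fh.write(f"{name}\t{lab}\n")
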