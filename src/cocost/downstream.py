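"""Spatial-domain assignment from contrastive components.

Clusters spot embeddings into spatial domains.  The default path clusters
the components directly with seeded k-means so results are exactly
reproducible; a graph-based Louvain-style alternative (k-means-free) is
provided for workflows that prefer community detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

ClusterMethod = Literal["kmeans", "graph_louvain"]


@dataclass
class DomainAssignment:
    """Per-spot integer domain labels, relabeled by descending cluster size."""

    spot_ids: list[str]
    labels: np.ndarray
    method: ClusterMethod
    params: dict
    seed: int

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self, embedding: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"spot_id": self.spot_ids, "domain": self.labels})
        if embedding is not None:
            for j in range(embedding.shape[1]):
                df[f"CC{j + 1}"] = embedding[:, j]
        return df

    def write(self, path: str | Path, embedding: np.ndarray | None = None) -> Path:
        path = Path(path)
        self.to_frame(embedding).to_csv(path, sep="\t", index=False)
        return path


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map cluster ids to 0..K-1 by descending size (ties: lower original id)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    mapping = {ids[i]: rank for rank, i in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def cluster_embedding(
    Z: np.ndarray,
    spot_ids: Sequence[str] | None = None,
    method: ClusterMethod = "kmeans",
    n_clusters: int = 6,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> DomainAssignment:
    """Cluster an ``n x p`` embedding into spatial domains.

    ``kmeans`` uses ``n_clusters`` (10 restarts, seeded); ``graph_louvain``
    builds a kNN graph on the embedding and runs Louvain community
    detection at the given ``resolution`` (requires python-igraph).  Output
    labels are contiguous from 0 and ordered by descending domain size.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("embedding contains non-finite values")
    n = Z.shape[0]
    if spot_ids is None:
        spot_ids = [str(i) for i in range(n)]
    if len(spot_ids) != n:
        raise ValueError("spot_ids length mismatch")

    if method == "kmeans":
        if n_clusters > n:
            raise ValueError(f"n_clusters={n_clusters} exceeds {n} spots")
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        raw = km.fit_predict(Z)
        params = {"n_clusters": n_clusters}
    elif method == "graph_louvain":
        import random

        import igraph as ig

        ig.set_random_number_generator(random.Random(seed))
        adj = kneighbors_graph(Z, n_neighbors=min(n_neighbors, n - 1), mode="connectivity")
        adj = adj.maximum(adj.T).tocoo()
        edges = [(int(i), int(j)) for i, j, _ in zip(adj.row, adj.col, adj.data) if i < j]
        g = ig.Graph(n=n, edges=edges)
        comm = g.community_multilevel(resolution=resolution)
        raw = np.asarray(comm.membership, dtype=int)
        params = {"resolution": resolution, "n_neighbors": n_neighbors}
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    return DomainAssignment(
        spot_ids=[str(s) for s in spot_ids],
        labels=_relabel_by_size(raw),
        method=method,
        params=params,
        seed=seed,
    )
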