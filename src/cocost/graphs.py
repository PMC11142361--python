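"""kNN heat-kernel affinity graphs, normalized Laplacians, Laplacian filters.

Each slice gets a spot-spot graph built either from expression profiles
(``mode='molecular'``) or from the 2-D spot coordinates (``mode='spatial'``).
Edges connect i and j when either is among the other's k nearest neighbors
(OR symmetrization) and carry heat-kernel weights ``exp(-||p_i - p_j||^2/t)``.
The symmetric normalized Laplacian of that graph defines the smoothing
filter ``H = I - mu * Lbar`` used inside the contrastive scatter matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

GraphMode = Literal["molecular", "spatial"]


@dataclass
class AffinityGraph:
    """Symmetric nonnegative spot-spot affinity matrix.

    ``S`` is sparse ``n x n`` with entries in [0, 1], zero diagonal, and OR
    symmetrization so every row has at least ``k`` nonzeros whenever n > k.
    ``t`` is the resolved heat-kernel bandwidth (squared-distance units).
    """

    S: sp.csr_matrix
    k: int
    t: float
    mode: GraphMode

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class LaplacianFilter:
    """Smoothing operator ``H = I - mu * Lbar``.

    ``mu`` in [0, 1] controls smoothness; since the eigenvalues of the
    symmetric normalized Laplacian lie in [0, 2], those of ``H`` lie in
    [1 - 2 mu, 1].  ``mu = 0`` gives the identity (no smoothing, the plain
    contrastive-PCA limit).
    """

    H: sp.csr_matrix
    mu: float
    Lbar: sp.csr_matrix
    t: float | None = None  # bandwidth of the graph this filter came from

    @property
    def n(self) -> int:
        return self.H.shape[0]


def build_knn_affinity(
    points: np.ndarray,
    k: int,
    t: float | Literal["auto"] = "auto",
    mode: GraphMode = "molecular",
) -> AffinityGraph:
    """Build the OR-symmetrized kNN graph with heat-kernel weights.

    ``t='auto'`` resolves to the median squared distance to the k-th
    neighbor, a scale-free bandwidth heuristic; the resolved value is
    logged and stored on the returned graph.  Self-neighbors are excluded;
    coincident points receive weight 1 edges.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not (1 <= k < n):
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    # drop the self column; with exact duplicates "self" may not be column 0,
    # so remove one occurrence of each point's own index explicitly
    neigh_d = np.empty((n, k))
    neigh_i = np.empty((n, k), dtype=int)
    for i in range(n):
        cols = [c for c in range(k + 1) if idx[i, c] != i][:k]
        neigh_d[i] = dist[i, cols]
        neigh_i[i] = idx[i, cols]

    sq = neigh_d**2
    if t == "auto":
        t_resolved = float(np.median(sq[:, -1]))
        if t_resolved <= 0:
            t_resolved = 1.0  # all duplicate points; any bandwidth gives weight 1
        logger.info("heat-kernel bandwidth t resolved to %.6g (%s graph)", t_resolved, mode)
    else:
        t_resolved = float(t)
        if t_resolved <= 0:
            raise ValueError("t must be positive")

    w = np.exp(-sq / t_resolved)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((w.ravel(), (rows, neigh_i.ravel())), shape=(n, n))
    S = A.maximum(A.T)  # OR rule: weight depends only on distance
    S.setdiag(0)
    S.eliminate_zeros()
    return AffinityGraph(S=S.tocsr(), k=k, t=t_resolved, mode=mode)


def normalized_laplacian(graph: AffinityGraph | sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Symmetric normalized graph Laplacian ``Lbar = D^{-1/2} (D - S) D^{-1/2}``.

    Rows/columns of zero-degree nodes are set to zero (the node is left
    unsmoothed rather than raising), keeping spot indices aligned with the
    expression matrix.
    """
    S = graph.S if isinstance(graph, AffinityGraph) else sp.csr_matrix(graph)
    if (abs(S - S.T) > 1e-12 * max(1.0, abs(S).max())).nnz:
        raise ValueError("affinity matrix must be symmetric")
    deg = np.asarray(S.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        logger.warning("%d zero-degree node(s); their Laplacian rows set to 0", int(isolated.sum()))
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[isolated] = 0.0
    Dinv = sp.diags(dinv)
    Snorm = Dinv @ S @ Dinv
    eye = sp.diags(np.where(isolated, 0.0, 1.0))
    Lbar = (eye - Snorm).tocsr()
    return ((Lbar + Lbar.T) * 0.5).tocsr()  # enforce exact symmetry


def laplacian_filter(Lbar: sp.spmatrix | np.ndarray, mu: float) -> LaplacianFilter:
    """Form ``H = I - mu * Lbar`` for ``mu`` in [0, 1]."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu={mu} outside [0, 1]")
    Lbar = sp.csr_matrix(Lbar)
    n = Lbar.shape[0]
    H = (sp.identity(n, format="csr") - mu * Lbar).tocsr()
    return LaplacianFilter(H=H, mu=float(mu), Lbar=Lbar)


def slice_filter(
    dataset,
    mode: GraphMode,
    k: int,
    t: float | Literal["auto"],
    mu: float,
) -> LaplacianFilter:
    """Convenience: affinity graph -> Laplacian -> filter for one slice.

    ``mode='molecular'`` builds the graph on expression profiles,
    ``mode='spatial'`` on the 2-D coordinates.
    """
    points = dataset.expr if mode == "molecular" else dataset.coords
    graph = build_knn_affinity(points, k=k, t=t, mode=mode)
    filt = laplacian_filter(normalized_laplacian(graph), mu)
    filt.t = graph.t
    return filt
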