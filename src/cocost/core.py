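"""Linear contrastive model: the filtered-scatter eigenproblem.

With standardized genes-by-spots matrices ``Xb`` (background) and ``Xt``
(target) and per-slice Laplacian filters ``Hb``, ``Ht``, the model maximizes

    tr(W' Xt Ht Xt' W) - eta * tr(W' Xb Hb Xb' W)   subject to  W'W = I.

The stationary points are eigenvectors of the symmetric (generally
indefinite) contrast matrix ``M = Xt Ht Xt' - eta Xb Hb Xb'``; the fitted
projection keeps the eigenvectors with the algebraically largest
eigenvalues.  With ``mu1 = mu2 = 0`` the filters are identities and the
method reduces exactly to contrastive PCA; with ``eta = 0`` it is a
graph-smoothed PCA of the target alone.  Components with negative
eigenvalues point into background-dominated directions and are excluded by
default (they can be kept with ``include_negative=True``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh

from .graphs import GraphMode, LaplacianFilter, slice_filter
from .io import SpatialDataset

logger = logging.getLogger(__name__)

# above this gene count the dense symmetric solver gives way to an iterative
# one requesting the largest-algebraic end of the spectrum
_DENSE_EIG_LIMIT = 5000


@dataclass
class ContrastiveModel:
    """Fitted orthonormal projection from gene space to contrastive components.

    ``W`` is ``d x p`` with orthonormal columns ordered by descending
    eigenvalue of the contrast matrix; ``gene_ids`` fixes the gene order the
    projection expects.  The graph parameters actually used (including the
    resolved heat-kernel bandwidths ``t_b``, ``t_t``) are stored for full
    reproducibility.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    eta: float
    mu1: float
    mu2: float
    k: int
    t_b: float
    t_t: float
    gene_ids: list[str]
    graph_mode: GraphMode

    @property
    def p(self) -> int:
        return self.W.shape[1]

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]


def filtered_scatter(X: np.ndarray, H: LaplacianFilter | sp.spmatrix | np.ndarray) -> np.ndarray:
    """Graph-filtered scatter ``X H X'`` for a ``d x n`` matrix ``X``.

    Symmetry is enforced by averaging with the transpose, which removes
    rounding asymmetry from the two sparse products.
    """
    X = np.asarray(X, dtype=float)
    Hmat = H.H if isinstance(H, LaplacianFilter) else H
    if X.shape[1] != Hmat.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} spots but filter is {Hmat.shape[0]} x {Hmat.shape[1]}"
        )
    M = X @ (Hmat @ X.T) if sp.issparse(Hmat) else X @ np.asarray(Hmat) @ X.T
    return (M + M.T) / 2.0


def _check_pair(background: SpatialDataset, target: SpatialDataset) -> None:
    if background.gene_ids != target.gene_ids:
        raise ValueError(
            "background and target gene namespaces differ; run align_genes first"
        )


def contrast_matrix(
    background: SpatialDataset,
    target: SpatialDataset,
    eta: float = 1.0,
    mu1: float = 0.5,
    mu2: float = 0.5,
    k: int = 15,
    t: float | Literal["auto"] = "auto",
    graph_mode: GraphMode = "molecular",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, LaplacianFilter, LaplacianFilter]:
    """Build ``M = Xt Ht Xt' - eta Xb Hb Xb'`` and its two scatter terms.

    Returns ``(M, B_background, B_target, filter_b, filter_t)``.  Graphs are
    constructed independently per slice with the same ``k``/``t`` settings;
    an ``'auto'`` bandwidth resolves per slice.
    """
    _check_pair(background, target)
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    filt_b = slice_filter(background, graph_mode, k, t, mu1)
    filt_t = slice_filter(target, graph_mode, k, t, mu2)
    Bb = filtered_scatter(background.X, filt_b)
    Bt = filtered_scatter(target.X, filt_t)
    M = Bt - eta * Bb
    if not np.all(np.isfinite(M)):
        for name, B in (("background", Bb), ("target", Bt)):
            if not np.all(np.isfinite(B)):
                raise ValueError(f"non-finite entries in the {name} scatter matrix")
        raise ValueError("non-finite entries in the contrast matrix")
    return (M + M.T) / 2.0, Bb, Bt, filt_b, filt_t


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (lowest index on ties)."""
    W = W.copy()
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def _top_eigenpairs(M: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Algebraically largest p eigenpairs of a symmetric matrix, descending."""
    d = M.shape[0]
    if d <= _DENSE_EIG_LIMIT or p >= d - 1:
        vals, vecs = eigh(M)
        vals, vecs = vals[::-1], vecs[:, ::-1]
    else:
        # indefinite matrix: request largest-algebraic, not largest-magnitude
        vals, vecs = eigsh(M, k=p, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    return vals[:p], vecs[:, :p]


def fit(
    background: SpatialDataset,
    target: SpatialDataset,
    eta: float = 1.0,
    mu1: float = 0.5,
    mu2: float = 0.5,
    k: int = 15,
    t: float | Literal["auto"] = "auto",
    p: int = 30,
    graph_mode: GraphMode = "molecular",
    include_negative: bool = False,
) -> ContrastiveModel:
    """Fit the contrastive projection on an aligned, standardized slice pair.

    Parameters
    ----------
    eta:
        Contrastive trade-off; 0 ignores the background, larger values
        push components out of the background's high-variance directions.
    mu1, mu2:
        Laplacian-filter smoothing weights in [0, 1] for background and
        target graphs (0 disables smoothing, recovering contrastive PCA).
    k, t, graph_mode:
        kNN graph settings shared by both slices.
    p:
        Number of components requested (algebraically largest eigenvalues).
    include_negative:
        Keep components whose eigenvalue is negative.  These live in
        background-dominated directions; they carry some discriminant
        information but are excluded by default.
    """
    d = background.n_genes
    if not 1 <= p <= d:
        raise ValueError(f"p={p} must be in [1, {d}]")
    M, _, _, filt_b, filt_t = contrast_matrix(
        background, target, eta=eta, mu1=mu1, mu2=mu2, k=k, t=t, graph_mode=graph_mode
    )
    vals, vecs = _top_eigenpairs(M, p)
    if not include_negative:
        tol = 1e-10 * max(1.0, float(np.abs(vals).max(initial=0.0)))
        keep = vals >= -tol
        if not keep.all():
            logger.info(
                "dropping %d negative-eigenvalue component(s)", int((~keep).sum())
            )
        vals, vecs = vals[keep], vecs[:, keep]
        if vals.size == 0:
            raise ValueError(
                "all requested components have negative eigenvalues; "
                "lower eta or pass include_negative=True"
            )
    W = _fix_signs(vecs)
    logger.info("eigenvalue spectrum head: %s", np.array2string(vals[:5], precision=4))
    return ContrastiveModel(
        W=W,
        eigenvalues=vals,
        eta=float(eta),
        mu1=float(mu1),
        mu2=float(mu2),
        k=int(k),
        t_b=float(filt_b.t),
        t_t=float(filt_t.t),
        gene_ids=list(background.gene_ids),
        graph_mode=graph_mode,
    )


def transform(model: ContrastiveModel, ds: SpatialDataset) -> np.ndarray:
    """Project a slice onto the fitted components; returns ``n x p`` scores.

    The slice must contain every model gene (extra genes are ignored) and
    should be standardized with its own per-gene statistics.  Row order
    follows the slice's spot order.
    """
    sub = ds.subset_genes(model.gene_ids)
    return sub.expr @ model.W


def top_genes(
    model: ContrastiveModel, component: int, top_k: int = 20
) -> list[tuple[str, float, str]]:
    """Rank genes on one component by loading magnitude.

    ``component`` is 1-based.  Returns ``(gene, |weight|, sign)`` tuples
    sorted by magnitude descending, lexicographic gene order on ties;
    ``top_k`` larger than the gene count returns all genes.
    """
    if not 1 <= component <= model.p:
        raise ValueError(f"component {component} out of range 1..{model.p}")
    w = model.W[:, component - 1]
    order = sorted(
        range(model.n_genes), key=lambda j: (-abs(w[j]), model.gene_ids[j])
    )
    out = []
    for j in order[: min(top_k, model.n_genes)]:
        out.append((model.gene_ids[j], float(abs(w[j])), "+" if w[j] >= 0 else "-"))
    return out


def background_rayleigh(
    model: ContrastiveModel, background_scatter: np.ndarray
) -> np.ndarray:
    """Background energy ``w_i' B w_i`` of each component.

    Diagnostic for the contrastive trade-off: as eta grows, positive-
    eigenvalue components migrate toward the null space of the background
    scatter and these quadratic forms shrink toward zero.
    """
    B = np.asarray(background_scatter, dtype=float)
    return np.sum(model.W * (B @ model.W), axis=0)


def save_model(model: ContrastiveModel, directory: str | Path) -> Path:
    """Serialize a model to a directory (metadata JSON + TSV matrices)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "eta": model.eta,
        "mu1": model.mu1,
        "mu2": model.mu2,
        "k": model.k,
        "t_b": model.t_b,
        "t_t": model.t_t,
        "graph_mode": model.graph_mode,
        "p": model.p,
        "gene_ids": model.gene_ids,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(directory / "W.tsv", model.W, delimiter="\t", fmt="%.17g")
    np.savetxt(directory / "eigenvalues.tsv", model.eigenvalues, fmt="%.17g")
    return directory


def load_model(directory: str | Path) -> ContrastiveModel:
    """Inverse of :func:`save_model`."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    W = np.loadtxt(directory / "W.tsv", delimiter="\t", ndmin=2)
    eigenvalues = np.loadtxt(directory / "eigenvalues.tsv", ndmin=1)
    return ContrastiveModel(
        W=W,
        eigenvalues=eigenvalues,
        eta=meta["eta"],
        mu1=meta["mu1"],
        mu2=meta["mu2"],
        k=meta["k"],
        t_b=meta["t_b"],
        t_t=meta["t_t"],
        gene_ids=list(meta["gene_ids"]),
        graph_mode=meta["graph_mode"],
    )
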