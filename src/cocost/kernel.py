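"""Kernelized contrastive model in a reproducing-kernel Hilbert space.

The projection directions are expanded over the combined reference set
``q_1..q_N`` (target spots first, then background spots, N = n_t + n_b) as
``V = Phi_c A``.  Substituting into the contrastive objective yields the
generalized symmetric eigenproblem

    (K_ct H_t K_tc - eta K_cb H_b K_bc) A = Lambda (K_cc + rho I) A,

where ``K_cc`` is the reference Gram matrix, ``K_ct``/``K_cb`` are
reference-against-slice kernel blocks, and ``H_t``/``H_b`` are the same
Laplacian filters as in the linear model (graphs built in input space).
The ridge ``rho`` guarantees a nonsingular right-hand side when ``K_cc``
is rank deficient.  Columns of ``A`` are normalized so that
``A' K_cc A`` has unit diagonal, the RKHS analogue of orthonormal loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import eigh

from .graphs import GraphMode, slice_filter
from .io import SpatialDataset

logger = logging.getLogger(__name__)

KernelType = Literal["linear", "polynomial", "gaussian", "sigmoid", "tanh"]


@dataclass
class KernelSpec:
    """Kernel function specification.

    ``linear``: x'y.  ``polynomial``: (x'y + 1)^degree.  ``gaussian``:
    exp(-||x-y||^2 / sigma^2).  ``sigmoid``: x'y + gamma, an affine shift of
    the linear kernel; ``tanh`` provides the conventional sigmoid kernel
    tanh(x'y + gamma) as an alternative.
    """

    type: KernelType = "linear"
    degree: int = 2
    sigma: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.type == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian kernel requires sigma > 0")
        if self.type == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def __call__(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """Pairwise kernel matrix between rows of ``Xa`` and rows of ``Xb``."""
        Xa, Xb = np.asarray(Xa, float), np.asarray(Xb, float)
        if self.type == "linear":
            return Xa @ Xb.T
        if self.type == "polynomial":
            return (Xa @ Xb.T + 1.0) ** self.degree
        if self.type == "gaussian":
            sq = (
                np.sum(Xa**2, axis=1)[:, None]
                + np.sum(Xb**2, axis=1)[None, :]
                - 2.0 * Xa @ Xb.T
            )
            np.maximum(sq, 0.0, out=sq)
            return np.exp(-sq / self.sigma**2)
        if self.type == "sigmoid":
            return Xa @ Xb.T + self.gamma
        if self.type == "tanh":
            return np.tanh(Xa @ Xb.T + self.gamma)
        raise ValueError(f"unknown kernel type {self.type!r}")


@dataclass
class KernelModel:
    """Fitted kernel projection: coefficients over the reference spots.

    ``reference`` holds the combined standardized expression rows (target
    first, then background) so the model is self-contained for
    out-of-sample transformation; ``A`` is ``N x p``.
    """

    A: np.ndarray
    reference: np.ndarray
    kernel: KernelSpec
    rho: float
    eigenvalues: np.ndarray
    eta: float
    mu1: float
    mu2: float
    gene_ids: list[str]
    n_target: int
    n_background: int
    graph_mode: GraphMode = "molecular"

    @property
    def p(self) -> int:
        return self.A.shape[1]


def gram_matrices(
    background: SpatialDataset,
    target: SpatialDataset,
    kernel: KernelSpec,
) -> dict[str, np.ndarray]:
    """Kernel blocks over the combined reference (target rows first).

    Returns ``Kcc`` (N x N, symmetric PSD for the PSD kernel choices),
    ``Kct``/``Ktc`` (reference vs target) and ``Kcb``/``Kbc`` (reference vs
    background).
    """
    if background.gene_ids != target.gene_ids:
        raise ValueError("gene namespaces differ; run align_genes first")
    Q = np.vstack([target.expr, background.expr])
    Kcc = kernel(Q, Q)
    Kcc = (Kcc + Kcc.T) / 2.0
    Kct = kernel(Q, target.expr)
    Kcb = kernel(Q, background.expr)
    return {"Kcc": Kcc, "Kct": Kct, "Ktc": Kct.T, "Kcb": Kcb, "Kbc": Kcb.T}


def default_rho(Kcc: np.ndarray) -> float:
    """Ridge scaled to the mean kernel self-similarity: 1e-3 tr(Kcc)/N."""
    return 1e-3 * float(np.trace(Kcc)) / Kcc.shape[0]


def fit_kernel(
    background: SpatialDataset,
    target: SpatialDataset,
    kernel: KernelSpec | None = None,
    eta: float = 1.0,
    mu1: float = 0.5,
    mu2: float = 0.5,
    k: int = 15,
    t: float | Literal["auto"] = "auto",
    p: int = 30,
    rho: float | None = None,
    graph_mode: GraphMode = "molecular",
) -> KernelModel:
    """Fit the kernelized contrastive model.

    ``rho=None`` uses the trace-scaled default ridge; pass an explicit small
    value (or 0 for a full-rank Gram matrix) to control shrinkage.  The p
    returned components correspond to the algebraically largest generalized
    eigenvalues.
    """
    kernel = kernel or KernelSpec()
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    K = gram_matrices(background, target, kernel)
    N = K["Kcc"].shape[0]
    if not 1 <= p <= N:
        raise ValueError(f"p={p} must be in [1, {N}]")
    if rho is None:
        rho = default_rho(K["Kcc"])
    if rho < 0:
        raise ValueError("rho must be nonnegative")

    filt_b = slice_filter(background, graph_mode, k, t, mu1)
    filt_t = slice_filter(target, graph_mode, k, t, mu2)
    Ht = filt_t.H.toarray()
    Hb = filt_b.H.toarray()
    M = K["Kct"] @ Ht @ K["Ktc"] - eta * K["Kcb"] @ Hb @ K["Kbc"]
    M = (M + M.T) / 2.0
    rhs = K["Kcc"] + rho * np.eye(N)
    try:
        vals, vecs = eigh(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "right-hand side K_cc + rho*I is numerically singular; "
            "increase rho above 0"
        ) from exc
    order = np.argsort(vals)[::-1][:p]
    vals, A = vals[order], vecs[:, order]
    # normalize so A' Kcc A has unit diagonal (RKHS orthonormality)
    norms = np.sqrt(np.maximum(np.sum(A * (K["Kcc"] @ A), axis=0), 0.0))
    good = norms > 1e-12
    if not good.all():
        logger.warning(
            "%d component(s) have near-zero RKHS norm; left unnormalized",
            int((~good).sum()),
        )
    A = A / np.where(good, norms, 1.0)
    return KernelModel(
        A=A,
        reference=np.vstack([target.expr, background.expr]),
        kernel=kernel,
        rho=float(rho),
        eigenvalues=vals,
        eta=float(eta),
        mu1=float(mu1),
        mu2=float(mu2),
        gene_ids=list(background.gene_ids),
        n_target=target.n_spots,
        n_background=background.n_spots,
        graph_mode=graph_mode,
    )


def kernel_transform(model: KernelModel, ds: SpatialDataset) -> np.ndarray:
    """Project a slice: ``Z = K(slice, reference) A``, rows in spot order."""
    sub = ds.subset_genes(model.gene_ids)
    Kxr = model.kernel(sub.expr, model.reference)
    return Kxr @ model.A
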