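"""Normalization, highly-variable-gene selection, standardization, alignment.

The fitting pipeline expects both slices normalized, reduced to a shared
highly-variable gene set, and standardized so every gene has zero mean and
unit standard deviation across spots.  Variance is then comparable between
genes and the contrastive scatter difference is well scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .io import SpatialDataset

logger = logging.getLogger(__name__)

Normalization = Literal["log_cpm", "vst_like", "none"]


@dataclass
class PreprocessConfig:
    """Preprocessing recipe applied to both slices before fitting.

    ``n_hvg`` genes are retained (ranked on the target slice, applied to
    both).  ``log_cpm``: per-spot depth scaling to ``target_sum`` followed by
    log1p.  ``vst_like``: the same depth-scaled log transform, but HVG
    ranking uses a clipped standardized-variance statistic so that a few
    extreme spots cannot dominate a gene's dispersion.
    """

    n_hvg: int = 3000
    normalization: Normalization = "log_cpm"
    standardize: bool = True
    target_sum: float = 1e4

    def __post_init__(self) -> None:
        if self.n_hvg <= 0:
            raise ValueError("n_hvg must be positive")


def normalize(
    ds: SpatialDataset,
    method: Normalization = "log_cpm",
    target_sum: float = 1e4,
) -> SpatialDataset:
    """Depth-normalize counts per spot and log-transform.

    All-zero spots cannot be scaled and are dropped with a warning.  With
    ``method='none'`` values pass through unchanged (layer tag still
    advances, for pipelines whose input is already normalized).
    """
    if ds.layer_tag != "raw":
        raise ValueError(f"normalize expects a raw layer, got {ds.layer_tag!r}")
    if method == "none":
        return replace(ds, layer_tag="normalized")
    if method not in ("log_cpm", "vst_like"):
        raise ValueError(f"unknown normalization {method!r}")
    totals = ds.expr.sum(axis=1)
    nonzero = totals > 0
    if not np.all(nonzero):
        logger.warning("dropping %d all-zero spot(s)", int((~nonzero).sum()))
        ds = ds.subset_spots(np.flatnonzero(nonzero))
        totals = totals[nonzero]
    scaled = ds.expr / totals[:, None] * target_sum
    return replace(ds, expr=np.log1p(scaled), layer_tag="normalized")


def _clipped_standardized_variance(expr: np.ndarray) -> np.ndarray:
    """Variance of per-gene standardized values clipped at sqrt(n).

    Ranks genes by how much their dispersion exceeds a Gaussian baseline
    while capping the leverage of individual spots.
    """
    n = expr.shape[0]
    mean = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (expr - mean) / sd_safe
    np.clip(z, -np.sqrt(n), np.sqrt(n), out=z)
    stat = (z**2).sum(axis=0) / (n - 1)
    return np.where(sd > 0, stat * sd, 0.0)


def select_hvg(
    ds: SpatialDataset, n: int, method: Normalization = "log_cpm"
) -> SpatialDataset:
    """Keep the ``n`` most variable genes.

    Ranking statistic is the per-gene variance (``log_cpm``) or the clipped
    standardized variance (``vst_like``).  Ties at the cutoff are broken by
    lexicographic gene symbol, so the result is deterministic.
    """
    if ds.layer_tag != "normalized":
        raise ValueError("select_hvg expects a normalized layer")
    if n > ds.n_genes:
        raise ValueError(f"requested {n} HVGs but only {ds.n_genes} genes present")
    if method == "vst_like":
        stat = _clipped_standardized_variance(ds.expr)
    else:
        stat = ds.expr.var(axis=0, ddof=1)
    # sort by (-statistic, symbol): deterministic under equal variance
    order = sorted(range(ds.n_genes), key=lambda j: (-stat[j], ds.gene_ids[j]))
    keep = sorted(order[:n])  # preserve original column order
    return ds.subset_genes([ds.gene_ids[j] for j in keep])


def standardize(ds: SpatialDataset) -> SpatialDataset:
    """Scale every gene to mean 0, sample standard deviation 1 across spots.

    Zero-variance genes are set to all-zero and recorded in
    ``zero_variance_genes``.  Idempotent to within rounding.
    """
    if ds.layer_tag not in ("normalized", "standardized"):
        raise ValueError("standardize expects a normalized layer")
    mean = ds.expr.mean(axis=0)
    sd = ds.expr.std(axis=0, ddof=1)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    expr = (ds.expr - mean) / sd_safe
    expr[:, flat] = 0.0
    flagged = sorted(set(ds.zero_variance_genes) | {
        ds.gene_ids[j] for j in np.flatnonzero(flat)
    })
    return replace(ds, expr=expr, layer_tag="standardized", zero_variance_genes=flagged)


def align_genes(
    background: SpatialDataset, target: SpatialDataset
) -> tuple[SpatialDataset, SpatialDataset]:
    """Restrict both slices to their shared genes, in a common order.

    The order is the background's gene order filtered to the intersection,
    which is deterministic for fixed inputs.
    """
    shared_set = set(background.gene_ids) & set(target.gene_ids)
    if not shared_set:
        raise ValueError("background and target share no genes")
    shared = [g for g in background.gene_ids if g in shared_set]
    logger.info("gene intersection size: %d", len(shared))
    return background.subset_genes(shared), target.subset_genes(shared)


def preprocess_pair(
    background: SpatialDataset,
    target: SpatialDataset,
    config: PreprocessConfig | None = None,
) -> tuple[SpatialDataset, SpatialDataset]:
    """Full recipe: normalize both slices, align genes, select HVGs on the
    target, apply the gene set to both, standardize each slice with its own
    per-gene statistics."""
    config = config or PreprocessConfig()
    b = normalize(background, config.normalization, config.target_sum)
    t = normalize(target, config.normalization, config.target_sum)
    b, t = align_genes(b, t)
    n_hvg = min(config.n_hvg, t.n_genes)
    if n_hvg < config.n_hvg:
        logger.info("n_hvg reduced to %d shared genes", n_hvg)
    t = select_hvg(t, n_hvg, config.normalization)
    b = b.subset_genes(t.gene_ids)
    if config.standardize:
        b, t = standardize(b), standardize(t)
    return b, t
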