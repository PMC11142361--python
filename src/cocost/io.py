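"""Readers and writers for gene-spot matrices, coordinate tables and embeddings.

A slice is held as a :class:`SpatialDataset`: a dense spots-by-genes
expression matrix, a spots-by-2 coordinate matrix, and the gene / spot
identifier lists.  All model mathematics uses the genes-by-spots orientation
(``d x n``) so that scatter matrices are ``d x d``; :meth:`SpatialDataset.X`
exposes that view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

LayerTag = Literal["raw", "normalized", "standardized"]


@dataclass
class SpatialDataset:
    """One spatial transcriptomics slice.

    Attributes
    ----------
    expr:
        ``(n_spots, n_genes)`` expression matrix (counts or normalized values).
    coords:
        ``(n_spots, 2)`` spatial coordinates (array units or microns).
    gene_ids, spot_ids:
        Ordered unique identifiers matching the columns / rows of ``expr``.
    layer_tag:
        Which processing stage the values represent.
    zero_variance_genes:
        Gene symbols whose variance was zero at standardization time.
    """

    expr: np.ndarray
    coords: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    layer_tag: LayerTag = "raw"
    zero_variance_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        n, d = self.expr.shape
        if len(self.spot_ids) != n or self.coords.shape != (n, 2):
            raise ValueError(
                f"spot bookkeeping mismatch: expr has {n} rows, "
                f"{len(self.spot_ids)} spot ids, coords shape {self.coords.shape}"
            )
        if len(self.gene_ids) != d:
            raise ValueError(
                f"gene bookkeeping mismatch: expr has {d} columns, "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids contain duplicates")
        if self.layer_tag == "raw":
            if not np.all(np.isfinite(self.expr)) or np.any(self.expr < 0):
                raise ValueError("raw layer must be finite and nonnegative")
        elif not np.all(np.isfinite(self.expr)):
            raise ValueError(f"{self.layer_tag} layer contains NaN/Inf")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Genes-by-spots view (``d x n``) used by the model mathematics."""
        return self.expr.T

    def subset_genes(self, genes: Sequence[str]) -> "SpatialDataset":
        """Restrict to ``genes`` in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            shown = ", ".join(missing[:10])
            raise KeyError(f"{len(missing)} gene(s) absent from dataset: {shown}")
        cols = [index[g] for g in genes]
        return replace(
            self, expr=self.expr[:, cols], gene_ids=list(genes),
            zero_variance_genes=[g for g in self.zero_variance_genes if g in set(genes)],
        )

    def subset_spots(self, rows: np.ndarray) -> "SpatialDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            expr=self.expr[rows],
            coords=self.coords[rows],
            spot_ids=[self.spot_ids[i] for i in rows],
        )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _read_coords(
    coords_path: Path, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    df = _read_table(coords_path)
    cmap = {"spot_id": "spot_id", "x": "x", "y": "y"}
    if column_map:
        cmap.update(column_map)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        # Visium tissue_positions convention as a fallback mapping.
        visium = {
            "spot_id": "barcode",
            "x": "pxl_col_in_fullres",
            "y": "pxl_row_in_fullres",
        }
        if all(v in df.columns for v in visium.values()):
            cmap = visium
        else:
            raise ValueError(
                f"coordinate table {coords_path} lacks columns {missing}; "
                "pass column_map={'spot_id': ..., 'x': ..., 'y': ...}"
            )
    out = df[[cmap["spot_id"], cmap["x"], cmap["y"]]].copy()
    out.columns = ["spot_id", "x", "y"]
    out["spot_id"] = out["spot_id"].astype(str)
    return out


def _read_mtx_triplet(matrix_path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """10x-style triplet: matrix in MatrixMarket form plus gene and barcode lists."""
    try:
        mat = mmread(matrix_path)
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    folder = matrix_path.parent

    def _companion(stems: Sequence[str]) -> Path:
        for stem in stems:
            for ext in (".tsv", ".txt"):
                p = folder / f"{stem}{ext}"
                if p.exists():
                    return p
        raise FileNotFoundError(
            f"no companion file {stems} next to {matrix_path}"
        )

    genes_file = _companion(["features", "genes"])
    barcodes_file = _companion(["barcodes"])
    # 10x features.tsv carries (id, symbol, type); use the symbol column when present
    gdf = pd.read_csv(genes_file, sep="\t", header=None)
    genes = gdf.iloc[:, 1 if gdf.shape[1] > 1 else 0].astype(str).tolist()
    barcodes = (
        pd.read_csv(barcodes_file, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    )
    return np.asarray(mat.todense() if hasattr(mat, "todense") else mat), genes, barcodes


def read_dataset(
    matrix_path: str | Path,
    coords_path: str | Path,
    format: Literal["mtx_triplet", "delimited"] = "delimited",
    orientation: Literal["genes_by_spots", "spots_by_genes"] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from a matrix file and a coordinate table.

    ``orientation`` defaults to the dominant convention of each format:
    genes-by-spots for ``mtx_triplet`` (the 10x layout), spots-by-genes for
    ``delimited``.  Spots are joined to coordinates by barcode (inner join,
    matrix file order preserved); spots lacking coordinates are dropped with
    a logged count.
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)

    if format == "mtx_triplet":
        values, axis0, axis1 = _read_mtx_triplet(matrix_path)
        orientation = orientation or "genes_by_spots"
        if orientation == "genes_by_spots":
            genes, spots = axis0, axis1
            expr = values.T
        else:
            spots, genes = axis0, axis1
            expr = values
        if expr.shape != (len(spots), len(genes)):
            raise ValueError(
                f"matrix shape {values.shape} inconsistent with "
                f"{len(genes)} genes x {len(spots)} barcodes"
            )
    elif format == "delimited":
        df = _read_table(matrix_path)
        orientation = orientation or "spots_by_genes"
        first = df.columns[0]
        df = df.set_index(first)
        if orientation == "spots_by_genes":
            spots = df.index.astype(str).tolist()
            genes = [str(c) for c in df.columns]
            expr = df.to_numpy(dtype=float)
        else:
            genes = df.index.astype(str).tolist()
            spots = [str(c) for c in df.columns]
            expr = df.to_numpy(dtype=float).T
    else:
        raise ValueError(f"unknown format {format!r}")

    cdf = _read_coords(coords_path, column_map).set_index("spot_id")
    keep = [i for i, s in enumerate(spots) if s in cdf.index]
    if not keep:
        raise ValueError(
            "no overlapping spot barcodes between matrix and coordinate table"
        )
    dropped = len(spots) - len(keep)
    if dropped:
        logger.info("dropped %d spot(s) missing coordinates", dropped)
    spot_ids = [spots[i] for i in keep]
    expr = expr[keep]
    coords = cdf.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)
    return SpatialDataset(expr=expr, coords=coords, gene_ids=genes, spot_ids=spot_ids)


def write_embedding(Z: np.ndarray, spot_ids: Sequence[str], path: str | Path) -> Path:
    """Write an ``n x p`` embedding as a TSV with header ``spot_id, CC1..CCp``.

    Values are written with 17 significant digits so a round-trip read
    reproduces the matrix bit-for-bit.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("embedding must be 2-D with at least one component")
    if Z.shape[0] != len(spot_ids):
        raise ValueError(
            f"{Z.shape[0]} embedding rows but {len(spot_ids)} spot ids"
        )
    path = Path(path)
    cols = [f"CC{j + 1}" for j in range(Z.shape[1])]
    with open(path, "w") as fh:
        fh.write("spot_id\t" + "\t".join(cols) + "\n")
        for sid, row in zip(spot_ids, Z):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`write_embedding`; returns ``(Z, spot_ids)``."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str}, float_precision="round_trip")
    spot_ids = df["spot_id"].astype(str).tolist()
    Z = df.drop(columns="spot_id").to_numpy(dtype=float)
    return Z, spot_ids
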