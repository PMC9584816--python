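"""Core data types, Matrix Market I/O, normalization, QC and doublet-cluster rules."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


@dataclass
class GeneMatrix:
    """Sparse cell x gene count matrix with an optional log-normalized layer.

    ``counts`` holds raw nonnegative integer UMI counts (CSR, cells in rows);
    ``lognorm``, when present, is ``log1p(counts / total_c * scale)`` with the
    same sparsity support.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix
    lognorm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count entry")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
                bad = int(np.argmax(self.counts.data != np.round(self.counts.data)))
                raise FormatError(f"non-integer count entry (data index {bad})")
            self.counts = self.counts.astype(np.int64)
        if self.lognorm is not None:
            self.lognorm = sp.csr_matrix(self.lognorm)
            if self.lognorm.shape != self.counts.shape:
                raise FormatError("lognorm layer shape does not match counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes) -> np.ndarray:
        """Integer positions of ``genes`` in ``gene_ids`` (KeyError if absent)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_cells(self, idx: np.ndarray) -> "GeneMatrix":
        return GeneMatrix(
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            counts=self.counts[idx],
            lognorm=None if self.lognorm is None else self.lognorm[idx],
        )


CELL_TABLE_COLUMNS = [
    "cell_id",
    "sample_id",
    "dataset_id",
    "condition",
]


def validate_cell_table(cells: pd.DataFrame, gm: GeneMatrix | None = None) -> None:
    if "cell_id" not in cells.columns:
        raise FormatError("cell table lacks a cell_id column")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"duplicate cell_id in cell table: {dup!r}")
    if "mito_fraction" in cells.columns:
        mf = cells["mito_fraction"]
        if ((mf < 0) | (mf > 1)).any():
            raise FormatError("mito_fraction outside [0, 1]")
    if gm is not None:
        missing = set(cells["cell_id"]) - set(gm.cell_ids)
        if missing:
            raise FormatError(f"cell table ids absent from matrix: {sorted(missing)[:3]}")


def read_counts(mtx_path, genes_path, cells_path) -> GeneMatrix:
    """Read a cells x genes MTX plus gene/cell TSVs into a :class:`GeneMatrix`.

    ``genes_path`` is a headerless single-column TSV; ``cells_path`` has a
    header with at least a ``cell_id`` column. Round-trips losslessly with
    :func:`write_counts`.
    """
    mtx_path, genes_path, cells_path = Path(mtx_path), Path(genes_path), Path(cells_path)
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(p)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    cells_df = pd.read_csv(cells_path, sep="\t")
    if "cell_id" not in cells_df.columns:
        raise FormatError(f"{cells_path}: missing cell_id header column")
    cells = cells_df["cell_id"].astype(str).to_numpy()
    mat = scipy.io.mmread(str(mtx_path))
    if mat.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{mtx_path}: declares {mat.shape[0]} cells x {mat.shape[1]} genes but "
            f"TSVs list {len(cells)} cells and {len(genes)} genes"
        )
    return GeneMatrix(cell_ids=cells, gene_ids=genes, counts=sp.csr_matrix(mat))


def write_counts(gm: GeneMatrix, out_dir, cells: pd.DataFrame | None = None) -> None:
    """Write matrix.mtx, genes.tsv and cells.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), gm.counts.tocoo(), field="integer")
    pd.Series(gm.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
    if cells is None:
        cells = pd.DataFrame({"cell_id": gm.cell_ids})
    cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_cell_table(cells_path) -> pd.DataFrame:
    cells = pd.read_csv(cells_path, sep="\t")
    validate_cell_table(cells)
    return cells


def lognormalize(gm: GeneMatrix, scale: float = 10000.0) -> GeneMatrix:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    Sparsity support is preserved; raises on zero-total cells (run QC first).
    """
    totals = np.asarray(gm.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = gm.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(
            f"cell {bad!r} has zero total counts; apply qc_filter before normalizing"
        )
    norm = gm.counts.tocsr().astype(np.float64)
    # scale each row by scale / total; log1p on stored (nonzero) entries only
    row_scale = scale / totals
    norm = sp.diags(row_scale) @ norm
    norm.data = np.log1p(norm.data)
    return GeneMatrix(gm.cell_ids, gm.gene_ids, gm.counts, lognorm=norm.tocsr())


def qc_filter(
    gm: GeneMatrix,
    cells: pd.DataFrame,
    min_umi: int = 1000,
    max_mito: float = 0.1,
) -> tuple[GeneMatrix, pd.DataFrame]:
    """Keep cells with ``umi_count >= min_umi`` and ``mito_fraction <= max_mito``.

    Both boundaries are inclusive. Returns the consistently subset matrix and
    cell table.
    """
    validate_cell_table(cells, gm)
    for col in ("umi_count", "mito_fraction"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    keep = (cells["umi_count"] >= min_umi) & (cells["mito_fraction"] <= max_mito)
    n_removed = int((~keep).sum())
    logger.info("qc_filter removed %d of %d cells", n_removed, len(cells))
    if keep.sum() == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    kept_cells = cells.loc[keep].reset_index(drop=True)
    idx = gm.cell_index(kept_cells["cell_id"])
    return gm.subset_cells(idx), kept_cells


def select_hvgs(gm: GeneMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top ``n`` genes by standardized dispersion of the lognorm layer.

    Per-gene variance is z-scaled within ``n_bins`` mean-expression bins;
    ties break by lexicographic gene id. Deterministic.
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required; run lognormalize first")
    if n > gm.n_genes:
        warnings.warn(
            f"requested {n} HVGs but only {gm.n_genes} genes present; returning all",
            stacklevel=2,
        )
        n = gm.n_genes
    X = gm.lognorm
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)

    z = np.full(gm.n_genes, -np.inf)
    expressed = var > 0
    if expressed.any():
        ranks = pd.Series(mean[expressed]).rank(method="first")
        bins = np.ceil(ranks / (len(ranks) / n_bins)).astype(int)
        v = var[expressed]
        zi = np.empty_like(v)
        for b in np.unique(bins):
            m = bins.to_numpy() == b
            mu, sd = v[m].mean(), v[m].std()
            zi[m] = (v[m] - mu) / sd if sd > 0 else 0.0
        z[expressed] = zi

    order = sorted(range(gm.n_genes), key=lambda i: (-z[i], str(gm.gene_ids[i])))
    return [str(gm.gene_ids[i]) for i in order[:n]]


def pca_embed(gm: GeneMatrix, hvgs, n_pcs: int = 50) -> np.ndarray:
    """Deterministic PCA scores (cells x n_pcs) on centered/scaled lognorm HVGs.

    Sign convention: the largest-magnitude loading of each component is
    positive, so the embedding is reproducible bit-for-bit.
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required; run lognormalize first")
    hvgs = list(hvgs)
    if n_pcs > len(hvgs):
        raise ValueError(f"n_pcs={n_pcs} exceeds the {len(hvgs)} supplied HVGs")
    X = np.asarray(gm.lognorm[:, gm.gene_index(hvgs)].todense(), dtype=np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return (U * S) * flip


def pca_model(gm: GeneMatrix, hvgs, n_pcs: int = 50) -> dict:
    """PCA loadings plus per-gene center/scale, for projecting query data."""
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    hvgs = list(hvgs)
    if n_pcs > len(hvgs):
        raise ValueError(f"n_pcs={n_pcs} exceeds the {len(hvgs)} supplied HVGs")
    X = np.asarray(gm.lognorm[:, gm.gene_index(hvgs)].todense(), dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return {
        "genes": [str(g) for g in hvgs],
        "mean": mean,
        "sd": sd,
        "loadings": (Vt.T * flip),  # genes x n_pcs
        "reference_latent": (U * S) * flip,
    }


def _check_labels(cells: pd.DataFrame, cluster_labels) -> np.ndarray:
    labels = np.asarray(cluster_labels)
    if len(labels) != len(cells):
        raise ValueError(
            f"{len(labels)} cluster labels for {len(cells)} cells"
        )
    if pd.isna(labels).any():
        raise ValueError("missing cluster label")
    return labels


def flag_doublet_clusters(
    cells: pd.DataFrame, cluster_labels, threshold: float = 0.7
) -> set:
    """Clusters whose doublet fraction strictly exceeds ``threshold``.

    ``cells`` must carry a boolean ``is_doublet`` column (per-cell calls are
    the caller's responsibility).
    """
    if "is_doublet" not in cells.columns:
        raise ValueError("cells lacks an is_doublet column")
    labels = _check_labels(cells, cluster_labels)
    flagged = set()
    is_dbl = cells["is_doublet"].to_numpy(dtype=bool)
    for cl in np.unique(labels):
        m = labels == cl
        if is_dbl[m].mean() > threshold:
            flagged.add(cl)
    logger.info("flag_doublet_clusters: %d clusters above %.2f", len(flagged), threshold)
    return flagged


def flag_multisignature_clusters(
    gm: GeneMatrix, cluster_labels, sigs: dict, score_threshold: float
) -> set:
    """Clusters scoring above threshold for >= 2 class signatures (for review).

    The per-cluster class score is the mean over cells of the mean lognorm of
    that class's signature genes. Flagged clusters are reported, not removed.
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    if not sigs or any(len(g) == 0 for g in sigs.values()):
        raise ValueError("empty class signature set")
    labels = np.asarray(cluster_labels)
    if len(labels) != gm.n_cells:
        raise ValueError("cluster_labels length does not match matrix")
    per_cell = {}
    for cls, genes in sigs.items():
        idx = gm.gene_index(sorted(genes))
        per_cell[cls] = np.asarray(gm.lognorm[:, idx].mean(axis=1)).ravel()
    flagged = set()
    for cl in np.unique(labels):
        m = labels == cl
        n_high = sum(per_cell[cls][m].mean() > score_threshold for cls in sigs)
        if n_high >= 2:
            flagged.add(cl)
    return flagged
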