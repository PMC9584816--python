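"""Cross-modality comparison: per-gene and per-cluster Pearson correlation
of cluster-level mean expression between two measurement modalities."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from atlasforge.data_model import GeneMatrix

logger = logging.getLogger(__name__)

MIN_CELLS_PER_GROUP = 10


def pseudobulk(
    gm: GeneMatrix,
    labels,
    group_by=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean lognorm per (node[, group]) with cell counts.

    Returns ``(means, info)``: ``means`` indexed by node (or (node, group))
    with one column per gene; ``info`` carries ``n_cells`` and an
    ``omitted`` flag for groups under 10 cells.
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    labels = np.asarray(labels)
    if len(labels) != gm.n_cells:
        raise ValueError("labels length does not match matrix")
    if group_by is not None:
        group_by = np.asarray(group_by)
        keys = pd.MultiIndex.from_arrays([labels, group_by], names=["node", "group"])
    else:
        keys = pd.Index(labels, name="node")
    dense = pd.DataFrame(
        np.asarray(gm.lognorm.todense()), columns=gm.gene_ids, index=keys
    )
    means = dense.groupby(level=list(range(keys.nlevels))).mean()
    n_cells = dense.groupby(level=list(range(keys.nlevels))).size()
    info = pd.DataFrame({"n_cells": n_cells})
    info["omitted"] = info["n_cells"] < MIN_CELLS_PER_GROUP
    return means, info


def expression_fractions(gm: GeneMatrix, labels) -> pd.DataFrame:
    """Fraction of expressing cells (count > 0) per (node, gene)."""
    labels = np.asarray(labels)
    dense = pd.DataFrame(
        np.asarray((gm.counts > 0).todense()), columns=gm.gene_ids, index=labels
    )
    return dense.groupby(level=0).mean()


def gene_filter(
    pb: pd.DataFrame,
    pct_table: pd.DataFrame,
    pct_min: float = 0.2,
    mean_min: float = 0.2,
) -> list:
    """Genes expressed in > ``pct_min`` of cells of some cluster OR with mean
    lognorm > ``mean_min`` in some cluster."""
    by_pct = (pct_table > pct_min).any(axis=0)
    by_mean = (pb > mean_min).any(axis=0)
    keep = by_pct.reindex(pb.columns, fill_value=False) | by_mean
    return [str(g) for g in pb.columns[keep]]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def per_gene_correlation(
    pb_a: pd.DataFrame,
    pb_b: pd.DataFrame,
    genes,
    omitted_nodes=(),
    min_nodes: int = 3,
) -> pd.Series:
    """Pearson r over shared clusters of per-cluster mean expression.

    Zero-variance or under-covered genes come back NaN (never imputed).
    """
    shared = [n for n in pb_a.index if n in set(pb_b.index) and n not in set(omitted_nodes)]
    if not shared:
        raise ValueError("no shared cluster between modalities")
    out = {}
    for g in genes:
        if g not in pb_a.columns or g not in pb_b.columns:
            out[g] = np.nan
            continue
        a = pb_a.loc[shared, g].to_numpy(dtype=float)
        b = pb_b.loc[shared, g].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_nodes:
            out[g] = np.nan
            continue
        out[g] = _pearson(a[ok], b[ok])
    return pd.Series(out, name="r")


def class_summary(gene_r: pd.Series, gene_class_map: dict) -> pd.Series:
    """Mean per-gene r per gene class (NaN r dropped)."""
    df = pd.DataFrame({"r": gene_r})
    df["cls"] = [gene_class_map.get(g) for g in df.index]
    return df.dropna().groupby("cls")["r"].mean()


def per_cluster_correlation(
    pb_a: pd.DataFrame,
    pb_b: pd.DataFrame,
    markers: pd.DataFrame,
    gene_r: pd.Series,
    spec_min: float = 0.25,
    r_min: float = 0.3,
    min_markers: int = 3,
    reference: str = "all",
) -> pd.Series:
    """Per-cluster Pearson r across that cluster's filtered marker genes.

    Markers must pass ``specificity > spec_min`` and cross-modality
    ``r > r_min``; clusters with fewer than ``min_markers`` eligible genes
    are NaN.
    """
    out = {}
    mk = markers[markers["reference"] == reference]
    for node in pb_a.index:
        if node not in set(pb_b.index):
            out[node] = np.nan
            continue
        node_mk = mk[(mk["node_id"] == node) & (mk["specificity"] > spec_min)]
        genes = [
            g
            for g in node_mk["gene"].astype(str)
            if g in gene_r.index and np.isfinite(gene_r[g]) and gene_r[g] > r_min
            and g in pb_a.columns and g in pb_b.columns
        ]
        if len(genes) < min_markers:
            out[node] = np.nan
            continue
        out[node] = _pearson(
            pb_a.loc[node, genes].to_numpy(dtype=float),
            pb_b.loc[node, genes].to_numpy(dtype=float),
        )
    return pd.Series(out, name="r")
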