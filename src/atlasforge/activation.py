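"""Condition-dependent activation scoring from immediate-early genes (IEGs)
and per-cluster differential expression with cross-cluster overlap."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from atlasforge.data_model import GeneMatrix
from atlasforge.markers import expression_stats

logger = logging.getLogger(__name__)


def filter_ieg_panel(
    gm: GeneMatrix, ieg_list, min_cells: int, max_cells: int
) -> list:
    """IEGs expressed (count > 0) in more than ``min_cells`` and at most
    ``max_cells`` cells."""
    present = [g for g in ieg_list if g in set(gm.gene_ids)]
    if not present:
        raise ValueError("no IEG from the list is present in the matrix")
    idx = gm.gene_index(present)
    n_expr = np.asarray((gm.counts[:, idx] > 0).sum(axis=0)).ravel()
    panel = [g for g, n in zip(present, n_expr) if min_cells < n <= max_cells]
    if not panel:
        raise ValueError("IEG panel empty after expression filtering")
    return panel


@dataclass
class ActivationRow:
    node_id: str
    n_iegs_expressed: int
    n_iegs_up: int
    pct_up: float
    mean_log2fc: float
    n_cells: int


def _condition_split(cells: pd.DataFrame, node_idx: np.ndarray):
    cond = cells["condition"].to_numpy()[node_idx]
    fasted = node_idx[cond == "fasted"]
    fed = node_idx[cond == "fed"]
    return fasted, fed


def _rank_sum_genes(X: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation rank-sum p per column."""
    from atlasforge.markers import van_elteren_genes

    _, p = van_elteren_genes(X, in_mask, np.zeros(X.shape[0], dtype=int))
    return p


def cluster_activation(
    gm: GeneMatrix,
    cells: pd.DataFrame,
    node_idx: np.ndarray,
    panel: list,
    node_id: str = "",
    alpha: float = 0.05,
    min_pct: float = 0.1,
    bonferroni_n: int | None = None,
) -> ActivationRow | None:
    """Fraction of expressed panel IEGs significantly up-regulated in the
    fasted condition within one node.

    An IEG counts as expressed when present in >= ``min_pct`` of the node's
    cells in either condition; Bonferroni uses ``bonferroni_n`` tests (the
    run-wide total) or the per-node expressed count when not given.
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    node_idx = np.asarray(node_idx, dtype=int)
    fasted, fed = _condition_split(cells, node_idx)
    if len(fasted) == 0 or len(fed) == 0:
        warnings.warn(f"node {node_id}: one condition absent; skipped", stacklevel=2)
        return None
    gidx = gm.gene_index(panel)
    pct_fa = np.asarray((gm.counts[fasted][:, gidx] > 0).mean(axis=0)).ravel()
    pct_fe = np.asarray((gm.counts[fed][:, gidx] > 0).mean(axis=0)).ravel()
    expressed = np.maximum(pct_fa, pct_fe) >= min_pct
    n_expr = int(expressed.sum())
    if n_expr == 0:
        return ActivationRow(node_id, 0, 0, np.nan, np.nan, len(node_idx))
    sel = gidx[expressed]
    stats = expression_stats(gm, fasted, fed)
    lfc = stats["avg_log2fc"].to_numpy()[sel]
    both = np.concatenate([fasted, fed])
    X = np.asarray(gm.lognorm[both][:, sel].todense())
    in_mask = np.zeros(len(both), dtype=bool)
    in_mask[: len(fasted)] = True
    p = _rank_sum_genes(X, in_mask)
    n_tests = bonferroni_n if bonferroni_n is not None else n_expr
    p_adj = np.minimum(1.0, p * n_tests)
    up = (p_adj < alpha) & (lfc > 0)
    return ActivationRow(
        node_id=node_id,
        n_iegs_expressed=n_expr,
        n_iegs_up=int(up.sum()),
        pct_up=float(up.mean()),
        mean_log2fc=float(lfc.mean()),
        n_cells=len(node_idx),
    )


def activation_table(
    gm: GeneMatrix,
    cells: pd.DataFrame,
    tree,
    level: int,
    panel: list,
    alpha: float = 0.05,
    min_pct: float = 0.1,
    per_node_correction: bool = False,
) -> pd.DataFrame:
    """Activation rows for every node at one tree level.

    By default Bonferroni corrects over all (node, gene) tests in the run;
    ``per_node_correction`` restricts the denominator to each node's
    expressed panel.
    """
    nodes = tree.nodes_at(level)
    bonferroni_n = None
    if not per_node_correction:
        bonferroni_n = len(panel) * len(nodes)
    rows = []
    for node in nodes:
        row = cluster_activation(
            gm, cells, tree.cells_of(node), panel, node, alpha, min_pct, bonferroni_n
        )
        if row is not None:
            rows.append(vars(row))
    return pd.DataFrame(rows)


def cluster_deg(
    gm: GeneMatrix,
    cells: pd.DataFrame,
    node_idx: np.ndarray,
    node_id: str = "",
    alpha: float = 0.05,
    min_pct: float = 0.1,
    min_cells: int = 3,
) -> pd.DataFrame | None:
    """Fasted-vs-fed rank-sum DE over a node's expressed genes
    (>= ``min_pct`` of cells in either condition), Bonferroni-corrected."""
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    node_idx = np.asarray(node_idx, dtype=int)
    fasted, fed = _condition_split(cells, node_idx)
    if len(fasted) < min_cells or len(fed) < min_cells:
        warnings.warn(f"node {node_id}: too few cells per condition; skipped", stacklevel=2)
        return None
    pct_fa = np.asarray((gm.counts[fasted] > 0).mean(axis=0)).ravel()
    pct_fe = np.asarray((gm.counts[fed] > 0).mean(axis=0)).ravel()
    expressed = np.maximum(pct_fa, pct_fe) >= min_pct
    sel = np.flatnonzero(expressed)
    if len(sel) == 0:
        return pd.DataFrame(columns=["gene", "log2fc", "p", "p_adj", "significant"])
    stats = expression_stats(gm, fasted, fed)
    lfc = stats["avg_log2fc"].to_numpy()[sel]
    both = np.concatenate([fasted, fed])
    X = np.asarray(gm.lognorm[both][:, sel].todense())
    in_mask = np.zeros(len(both), dtype=bool)
    in_mask[: len(fasted)] = True
    p = _rank_sum_genes(X, in_mask)
    p_adj = np.minimum(1.0, p * len(sel))
    return pd.DataFrame(
        {
            "gene": gm.gene_ids[sel],
            "log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )


def deg_overlap(deg_tables: dict, fractions=(0.2, 0.5)) -> dict:
    """Genes significantly regulated in at least each given fraction of nodes.

    ``deg_tables`` maps node id -> DEG table from :func:`cluster_deg`.
    Returns ``{fraction: sorted gene list}`` plus per-gene node fractions
    under the key ``"per_gene"``.
    """
    if len(deg_tables) < 2:
        raise ValueError("need DEG tables from at least 2 nodes")
    n_nodes = len(deg_tables)
    counts: dict = {}
    for tab in deg_tables.values():
        for g in tab.loc[tab["significant"], "gene"]:
            counts[g] = counts.get(g, 0) + 1
    per_gene = {g: c / n_nodes for g, c in counts.items()}
    out: dict = {"per_gene": per_gene}
    for f in fractions:
        out[f] = sorted(g for g, frac in per_gene.items() if frac >= f)
    return out
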