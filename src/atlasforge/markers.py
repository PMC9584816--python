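"""Stratified rank-sum (van Elteren) marker testing and specificity scoring.

The van Elteren statistic combines per-stratum Wilcoxon rank sums with
"locally best" weights w_h = 1/(n_h + 1) and a tie-corrected variance;
with one stratum it reduces exactly to the normal-approximation
Mann-Whitney test. Specificity S = avg_log2FC * pct_in / pct_out (floored).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from atlasforge.data_model import GeneMatrix


def _stratum_terms(values: np.ndarray, in_mask: np.ndarray) -> tuple[float, float, float, float]:
    """(W, E[W], Var(W), w) for one stratum; tie-corrected variance."""
    n = len(values)
    n_in = int(in_mask.sum())
    n_out = n - n_in
    ranks = scipy.stats.rankdata(values)
    w_stat = float(ranks[in_mask].sum())
    e_w = n_in * (n + 1) / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_w = n_in * n_out / 12.0 * ((n + 1) - tie_term)
    weight = 1.0 / (n + 1)
    return w_stat, e_w, var_w, weight


def van_elteren(values, in_mask, strata) -> tuple[float, float]:
    """Two-sided stratified rank-sum test.

    Strata lacking either group are skipped; at least one usable stratum is
    required. All-tied data gives (z=0, p=1).
    """
    values = np.asarray(values, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    strata = np.asarray(strata)
    num = 0.0
    den = 0.0
    usable = 0
    for h in np.unique(strata):
        m = strata == h
        im = in_mask[m]
        if im.sum() == 0 or im.sum() == m.sum():
            continue
        usable += 1
        w_stat, e_w, var_w, weight = _stratum_terms(values[m], im)
        num += weight * (w_stat - e_w)
        den += weight**2 * var_w
    if usable == 0:
        raise ValueError("no stratum contains both groups")
    if den <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(den)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(max(p, np.nextafter(0, 1)))


def van_elteren_genes(
    X: np.ndarray, in_mask: np.ndarray, strata: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized van Elteren over the columns of a dense cells x genes block."""
    in_mask = np.asarray(in_mask, dtype=bool)
    strata = np.asarray(strata)
    n_genes = X.shape[1]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    usable = 0
    for h in np.unique(strata):
        m = strata == h
        im = in_mask[m]
        n = int(m.sum())
        n_in = int(im.sum())
        n_out = n - n_in
        if n_in == 0 or n_out == 0:
            continue
        usable += 1
        sub = X[m]
        ranks = scipy.stats.rankdata(sub, axis=0)
        w_stat = ranks[im].sum(axis=0)
        e_w = n_in * (n + 1) / 2.0
        tie = np.empty(n_genes)
        srt = np.sort(sub, axis=0)
        for g in range(n_genes):
            _, counts = np.unique(srt[:, g], return_counts=True)
            tie[g] = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        var_w = n_in * n_out / 12.0 * ((n + 1) - tie)
        weight = 1.0 / (n + 1)
        num += weight * (w_stat - e_w)
        den += weight**2 * var_w
    if usable == 0:
        raise ValueError("no stratum contains both groups")
    z = np.zeros(n_genes)
    ok = den > 0
    z[ok] = num[ok] / np.sqrt(den[ok])
    p = np.where(ok, 2.0 * scipy.stats.norm.sf(np.abs(z)), 1.0)
    return z, np.maximum(p, np.nextafter(0, 1))


def expression_stats(
    gm: GeneMatrix, node_cells: np.ndarray, ref_cells: np.ndarray
) -> pd.DataFrame:
    """Per-gene (avg_log2fc, pct_in, pct_out) of node vs reference cells.

    Fold change is computed on de-logged normalized means with pseudocount 1:
    log2((mean expm1(lognorm)_node + 1) / (mean expm1(lognorm)_ref + 1)).
    """
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    node_cells = np.asarray(node_cells, dtype=int)
    ref_cells = np.asarray(ref_cells, dtype=int)
    if len(node_cells) == 0 or len(ref_cells) == 0:
        raise ValueError("empty cell set")
    if set(node_cells) & set(ref_cells):
        raise ValueError("node and reference cells overlap")
    expm1 = gm.lognorm.copy()
    expm1.data = np.expm1(expm1.data)
    mean_in = np.asarray(expm1[node_cells].mean(axis=0)).ravel()
    mean_out = np.asarray(expm1[ref_cells].mean(axis=0)).ravel()
    pct_in = np.asarray((gm.counts[node_cells] > 0).mean(axis=0)).ravel()
    pct_out = np.asarray((gm.counts[ref_cells] > 0).mean(axis=0)).ravel()
    lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    return pd.DataFrame(
        {
            "gene": gm.gene_ids,
            "avg_log2fc": lfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
        }
    )


def specificity(avg_log2fc, pct_in, pct_out, n_ref: int):
    """S = avg_log2FC * pct_in / max(pct_out, 1/n_ref)."""
    if np.any(np.asarray(n_ref) <= 0):
        raise ValueError("n_ref must be > 0")
    floor = 1.0 / n_ref
    return np.asarray(avg_log2fc) * np.asarray(pct_in) / np.maximum(pct_out, floor)


def _compare(
    gm: GeneMatrix,
    node_idx: np.ndarray,
    ref_idx: np.ndarray,
    strata: np.ndarray,
    min_pct: float,
    min_abs_lfc: float,
) -> pd.DataFrame:
    stats = expression_stats(gm, node_idx, ref_idx)
    tested = (
        (np.maximum(stats["pct_in"], stats["pct_out"]) >= min_pct)
        & (np.abs(stats["avg_log2fc"]) >= min_abs_lfc)
    ).to_numpy()
    n_tests = int(tested.sum())
    out = stats.loc[tested].reset_index(drop=True)
    if n_tests == 0:
        out["z"] = out["p"] = out["p_adj"] = out["specificity"] = np.array([])
        return out
    all_idx = np.concatenate([node_idx, ref_idx])
    gidx = np.flatnonzero(tested)
    X = np.asarray(gm.lognorm[all_idx][:, gidx].todense())
    in_mask = np.zeros(len(all_idx), dtype=bool)
    in_mask[: len(node_idx)] = True
    z, p = van_elteren_genes(X, in_mask, strata[all_idx])
    out["z"] = z
    out["p"] = p
    out["p_adj"] = np.minimum(1.0, p * n_tests)
    out["specificity"] = specificity(
        out["avg_log2fc"], out["pct_in"], out["pct_out"], len(ref_idx)
    )
    return out


def sibling_markers(
    gm: GeneMatrix,
    cells_by_node: dict,
    strata=None,
    min_pct: float = 0.1,
    min_abs_lfc: float = 0.25,
) -> pd.DataFrame:
    """Vs-siblings marker table for one sibling set (node -> cell indices)."""
    strata = _as_strata(gm, strata)
    frames = []
    nodes = sorted(cells_by_node)
    for node in nodes:
        node_idx = np.asarray(cells_by_node[node], dtype=int)
        ref_idx = np.concatenate(
            [np.asarray(cells_by_node[o], dtype=int) for o in nodes if o != node]
        )
        res = _compare(gm, node_idx, ref_idx, strata, min_pct, min_abs_lfc)
        res.insert(1, "node_id", node)
        res.insert(2, "reference", "siblings")
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def _as_strata(gm: GeneMatrix, strata) -> np.ndarray:
    if strata is None:
        return np.zeros(gm.n_cells, dtype=int)
    strata = np.asarray(strata)
    if len(strata) != gm.n_cells:
        raise ValueError("strata length does not match matrix")
    return strata


def markers_for_tree(
    gm: GeneMatrix,
    tree,
    strata=None,
    min_pct: float = 0.1,
    min_abs_lfc: float = 0.25,
    subtree_level: int = 1,
    references: tuple = ("all", "siblings"),
) -> pd.DataFrame:
    """Marker table for every tree node vs (a) all other cells of its subtree
    at the same level and (b) its sibling cells.

    ``subtree_level`` is the level whose nodes define the restriction
    subtrees for the "all" reference (the root split of the atlas); nodes at
    or above it are compared against the full complement. Bonferroni
    correction is applied per comparison over its tested genes.
    """
    strata = _as_strata(gm, strata)
    frames = []
    for level in range(tree.n_levels):
        labels = tree.level_labels(level)
        if subtree_level < level and subtree_level >= 0:
            subtree_of = tree.level_labels(subtree_level)
        else:
            subtree_of = np.zeros(gm.n_cells, dtype=int)
        for node in np.unique(labels):
            node_mask = labels == node
            node_idx = np.flatnonzero(node_mask)
            sub = subtree_of[node_idx[0]]
            if "all" in references:
                ref_mask = (~node_mask) & (subtree_of == sub)
                if ref_mask.any():
                    res = _compare(
                        gm, node_idx, np.flatnonzero(ref_mask), strata, min_pct, min_abs_lfc
                    )
                    res.insert(1, "node_id", node)
                    res.insert(2, "reference", "all")
                    res["level"] = level
                    frames.append(res)
            if "siblings" in references:
                # level-0 nodes are mutual siblings under the implicit root
                if level > 0:
                    parent_labels = tree.level_labels(level - 1)
                    sib_mask = (parent_labels == parent_labels[node_idx[0]]) & (~node_mask)
                else:
                    sib_mask = ~node_mask
                if sib_mask.any():
                    res = _compare(
                        gm, node_idx, np.flatnonzero(sib_mask), strata, min_pct, min_abs_lfc
                    )
                    res.insert(1, "node_id", node)
                    res.insert(2, "reference", "siblings")
                    res["level"] = level
                    frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene", "node_id", "reference", "avg_log2fc", "pct_in",
                "pct_out", "z", "p", "p_adj", "specificity", "level",
            ]
        )
    return pd.concat(frames, ignore_index=True)
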