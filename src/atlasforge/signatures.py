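"""Bulk signature construction and extrapolated rank-biased overlap (RBO)
mapping of ranked signatures onto cluster marker lists."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def build_signature(de_table: pd.DataFrame, p_adj_max: float = 0.05) -> list:
    """Ranked signature: genes with p_adj < threshold and log2FC > 0, sorted
    by descending log2FC (ties lexicographic)."""
    for col in ("gene", "log2FC", "p_adj"):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    keep = de_table[(de_table["p_adj"] < p_adj_max) & (de_table["log2FC"] > 0)]
    if keep.empty:
        raise ValueError("no significantly enriched gene in DE table")
    keep = keep.sort_values(
        ["log2FC", "gene"], ascending=[False, True], kind="mergesort"
    )
    genes = keep["gene"].astype(str).tolist()
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in DE table")
    return genes


def rbo_ext(S: list, L: list, p: float) -> float:
    """Extrapolated rank-biased overlap for uneven duplicate-free lists.

    With s = |S| <= l = |L| (lists swapped otherwise) and
    X_d = |S[:min(d, s)] ∩ L[:d]|:

        RBO = (1-p)/p * [ sum_{d=1}^{l} X_d/d p^d
                          + sum_{d=s+1}^{l} X_s (d-s)/(s d) p^d ]
              + [ (X_l - X_s)/l + X_s/s ] p^l
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    S, L = list(S), list(L)
    if len(set(S)) != len(S) or len(set(L)) != len(L):
        raise ValueError("lists must be duplicate-free")
    if len(S) > len(L):
        S, L = L, S
    s, l = len(S), len(L)
    if l == 0:
        raise ValueError("empty lists")
    s_set: set = set()
    l_set: set = set()
    x = np.zeros(l + 1)
    for d in range(1, l + 1):
        l_set.add(L[d - 1])
        if d <= s:
            s_set.add(S[d - 1])
        x[d] = len(s_set & l_set)
    d = np.arange(1, l + 1)
    pd_pow = p**d
    term1 = float((x[1:] / d * pd_pow).sum())
    term2 = 0.0
    if l > s:
        dd = np.arange(s + 1, l + 1)
        term2 = float((x[s] * (dd - s) / (s * dd) * p**dd).sum())
    tail = ((x[l] - x[s]) / l + x[s] / s) * p**l
    val = (1.0 - p) / p * (term1 + term2) + tail
    return float(min(max(val, 0.0), 1.0))


def node_ranked_markers(
    markers: pd.DataFrame,
    node: str,
    rank_key: str = "log2fc",
    p_adj_max: float = 0.05,
) -> list:
    """Vs-all markers of a node, ranked descending by log2FC or specificity."""
    key = {"log2fc": "avg_log2fc", "specificity": "specificity"}[rank_key]
    m = markers[
        (markers["node_id"] == node)
        & (markers["reference"] == "all")
        & (markers["p_adj"] < p_adj_max)
        & (markers[key] > 0)
    ]
    m = m.sort_values([key, "gene"], ascending=[False, True], kind="mergesort")
    return m["gene"].astype(str).tolist()


def enrich_tree(
    signature: list,
    markers: pd.DataFrame,
    tree,
    level: int,
    rank_key: str = "log2fc",
    p: float = 0.98,
) -> pd.DataFrame:
    """RBO of the signature against each node's ranked marker list at one
    tree level; ``relative_rbo`` rescales to the per-level maximum."""
    rows = []
    for node in tree.nodes_at(level):
        ranked = node_ranked_markers(markers, node, rank_key)
        if not ranked:
            warnings.warn(f"node {node} has no markers; rbo set to 0", stacklevel=2)
            rows.append({"node_id": node, "rbo": 0.0})
            continue
        rows.append({"node_id": node, "rbo": rbo_ext(signature, ranked, p)})
    out = pd.DataFrame(rows)
    mx = out["rbo"].max()
    out["relative_rbo"] = out["rbo"] / mx if mx > 0 else 0.0
    return out.sort_values("rbo", ascending=False).reset_index(drop=True)
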