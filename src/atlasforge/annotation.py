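"""Marker-based node naming: T score and hierarchical name construction."""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSIONS = ("^mt-", "^Rp[ls]")


def naming_score(
    s_all: float, s_sib: float, child_s_sib: list | None
) -> float:
    """T = S_all * S_sib / max(1, max over children of that gene's
    vs-siblings specificity).

    Genes that really mark a sub-branch (a child with high vs-siblings
    specificity) are penalized; childless nodes use denominator 1. Children
    where the gene was untested contribute nothing, and the denominator is
    floored at 1 so only genuinely child-specific genes shrink T.
    """
    denom = 1.0
    if child_s_sib:
        denom = max(1.0, max(child_s_sib))
    return s_all * s_sib / denom


def _sib_spec_lookup(markers: pd.DataFrame) -> dict:
    sib = markers[markers["reference"] == "siblings"]
    return {
        (r.node_id, r.gene): r.specificity for r in sib.itertuples()
    }


def assign_names(
    tree,
    markers: pd.DataFrame,
    exclusions=DEFAULT_EXCLUSIONS,
    manual_names: dict | None = None,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Top-down marker-gene naming of every tree node.

    Candidates per node are its vs-siblings markers passing the p_adj
    filter, minus excluded-prefix genes and genes already chosen on the
    ancestor path; the winner maximizes T (ties: higher vs-all specificity,
    then lexicographic). ``full_name`` prepends the chosen gene to the
    parent's full name; siblingless nodes inherit the parent name unchanged.
    ``manual_names`` maps node ids of the hand-labeled top levels to fixed
    names.
    """
    manual_names = manual_names or {}
    patterns = [re.compile(p) for p in exclusions]
    sib = markers[markers["reference"] == "siblings"]
    allref = markers[markers["reference"] == "all"]
    s_all_of = {(r.node_id, r.gene): r.specificity for r in allref.itertuples()}
    sib_spec = _sib_spec_lookup(markers)

    rows = []
    full_name: dict = {}
    chosen_path: dict = {}  # node -> frozenset of genes used on its path

    for level in range(tree.n_levels):
        for node in tree.nodes_at(level):
            parent = tree.parent_of(node)
            parent_full = full_name.get(parent, "")
            used = chosen_path.get(parent, frozenset())
            if node in manual_names:
                name = manual_names[node]
                full = name if not parent_full else f"{name}.{parent_full}"
                full_name[node] = full
                chosen_path[node] = used
                rows.append({"node_id": node, "chosen_gene": None, "full_name": full})
                continue
            if not tree.siblings_of(node):
                full_name[node] = parent_full or node
                chosen_path[node] = used
                rows.append(
                    {"node_id": node, "chosen_gene": None, "full_name": full_name[node]}
                )
                continue
            cand = sib[(sib["node_id"] == node) & (sib["p_adj"] < p_adj_max)]
            cand = cand[cand["specificity"] > 0]
            children = tree.children_of(node)
            best = None  # (T, s_all, gene)
            for r in cand.itertuples():
                gene = r.gene
                if gene in used:
                    continue
                if any(p.search(str(gene)) for p in patterns):
                    continue
                s_all = s_all_of.get((node, gene), 0.0)
                child_vals = [
                    sib_spec[(c, gene)] for c in children if (c, gene) in sib_spec
                ]
                t = naming_score(s_all, r.specificity, child_vals)
                key = (t, s_all, _neg_lex(str(gene)))
                if best is None or key > best[0]:
                    best = (key, gene, t, s_all)
            if best is None:
                warnings.warn(f"no eligible name candidate for {node}; using id", stacklevel=2)
                gene = None
                full = node if not parent_full else f"{node}.{parent_full}"
            else:
                gene = best[1]
                full = gene if not parent_full else f"{gene}.{parent_full}"
            full_name[node] = full
            chosen_path[node] = used | ({gene} if gene else frozenset())
            rows.append({"node_id": node, "chosen_gene": gene, "full_name": full})
    return pd.DataFrame(rows)


class _neg_lex(str):
    """Wrapper ordering strings in reverse, so max() prefers lexicographically
    smaller gene ids on ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
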