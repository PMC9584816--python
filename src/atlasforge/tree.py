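"""Multi-resolution clustering ladder, nested tree reconciliation, pruning.

The tree is stored as one label vector per level with strict nesting
(finer levels refine coarser ones); node ids follow the ``C<levelsize>-<k>``
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class ClusterLevel:
    resolution: float
    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


class ClusterTree:
    """Nested multi-level partition of cells.

    Construct from per-cell label arrays (coarse to fine); nesting is
    validated. Node ids are ``C<levelsize>-<k>`` with ``k`` assigned in
    order of first appearance of the underlying label.
    """

    def __init__(self, level_labels: list):
        if len(level_labels) < 1:
            raise ValueError("need at least one level")
        arrays = [np.asarray(a) for a in level_labels]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("level label arrays differ in length")
        self._raw = arrays
        self._check_nesting()
        self._levels = []  # per-level node-id string arrays
        self._parent: dict = {}
        self._cells: dict = {}
        prev_ids = None
        seen_sizes: set = set()
        for lvl, arr in enumerate(arrays):
            uniq = pd.unique(arr)
            size = len(uniq)
            # ids are C<levelsize>-<k>; a repeated level size would collide
            # across levels, so such levels carry the level index too
            stem = f"C{size}" if size not in seen_sizes else f"C{size}.{lvl}"
            seen_sizes.add(size)
            id_of = {lab: f"{stem}-{k + 1}" for k, lab in enumerate(uniq)}
            ids = np.array([id_of[lab] for lab in arr], dtype=object)
            self._levels.append(ids)
            for lab in uniq:
                nid = id_of[lab]
                mask = arr == lab
                self._cells[nid] = np.flatnonzero(mask)
                if prev_ids is not None:
                    self._parent[nid] = prev_ids[self._cells[nid][0]]
            prev_ids = ids
        self._children: dict = {nid: [] for lvl in self._levels for nid in pd.unique(lvl)}
        for child, par in self._parent.items():
            self._children[par].append(child)

    def _check_nesting(self) -> None:
        for lvl in range(1, len(self._raw)):
            fine, coarse = self._raw[lvl], self._raw[lvl - 1]
            df = pd.DataFrame({"f": fine, "c": coarse})
            if (df.groupby("f", sort=False)["c"].nunique() > 1).any():
                raise ValueError(f"level {lvl} labels are not nested within level {lvl - 1}")

    @property
    def n_levels(self) -> int:
        return len(self._levels)

    @property
    def n_cells(self) -> int:
        return len(self._levels[0])

    def level_labels(self, level: int) -> np.ndarray:
        return self._levels[level]

    def nodes_at(self, level: int) -> list:
        return list(pd.unique(self._levels[level]))

    def all_nodes(self) -> list:
        return [n for lvl in range(self.n_levels) for n in self.nodes_at(lvl)]

    def level_of(self, node: str) -> int:
        for lvl in range(self.n_levels):
            if node in set(self.nodes_at(lvl)):
                return lvl
        raise KeyError(node)

    def parent_of(self, node: str):
        return self._parent.get(node)

    def children_of(self, node: str) -> list:
        return self._children.get(node, [])

    def siblings_of(self, node: str) -> list:
        """Other children of the node's parent; level-0 nodes (children of
        the implicit root) are siblings of each other."""
        par = self.parent_of(node)
        if par is None:
            if node in set(self.nodes_at(0)):
                return [n for n in self.nodes_at(0) if n != node]
            return []
        return [c for c in self.children_of(par) if c != node]

    def cells_of(self, node: str) -> np.ndarray:
        return self._cells[node]

    def to_dict(self) -> dict:
        return {
            "levels": [list(map(str, lvl)) for lvl in self._levels],
            "parents": {k: str(v) for k, v in self._parent.items()},
        }


def snn_graph(embedding: np.ndarray, k: int = 25, prune: float = 1.0 / 15.0) -> igraph.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets (self
    included), edges below ``prune`` dropped."""
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    # kneighbors() excludes self; prepend it so the set has k members like Seurat
    idx = np.hstack([np.arange(n)[:, None], idx[:, : k - 1]])
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jaccard = s / (2 * k - s)
    keep = jaccard >= prune
    g = igraph.Graph(
        n=n,
        edges=list(zip(r[keep].tolist(), c[keep].tolist())),
        edge_attrs={"weight": jaccard[keep].tolist()},
    )
    return g


def leiden_partition(graph: igraph.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Default community detector: Leiden with the RB-configuration objective."""
    import leidenalg

    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.edge_attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def multires_cluster(
    graph: igraph.Graph,
    resolutions,
    community_fn=leiden_partition,
    seed: int = 0,
) -> list:
    """One :class:`ClusterLevel` per resolution (sorted ascending)."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    out = []
    for r in sorted(resolutions):
        labels = community_fn(graph, r, seed)
        out.append(ClusterLevel(resolution=float(r), labels=np.asarray(labels)))
    return out


def select_levels(levels: list, base_levels: list, factor: float = 3.0) -> list:
    """Greedy ladder selection: after the supplied base levels, repeatedly
    pick the level whose cluster count is nearest ``factor`` x the previous
    pick; stop when no level adds clusters."""
    levels = sorted(levels, key=lambda lv: lv.n_clusters)
    if base_levels:
        prev = len(np.unique(np.asarray(base_levels[-1])))
    else:
        prev = 1
    selected = []
    used = set()
    while True:
        target = factor * prev
        candidates = [
            (abs(lv.n_clusters - target), lv.n_clusters, i)
            for i, lv in enumerate(levels)
            if i not in used and lv.n_clusters > prev
        ]
        if not candidates:
            break
        _, n, i = min(candidates)
        selected.append(levels[i])
        used.add(i)
        prev = n
    return selected


def reconcile_tree(level_label_arrays: list) -> ClusterTree:
    """Attach each finer cluster to the coarser cluster holding the plurality
    of its cells, then relabel coarser levels from the finest down so labels
    nest strictly. Ties break toward the larger coarse cluster, then
    lexicographically."""
    arrays = [np.asarray(a) for a in level_label_arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 levels")
    # parent maps computed on the original labels, pairwise
    parent_maps = []
    for lvl in range(1, len(arrays)):
        fine, coarse = arrays[lvl], arrays[lvl - 1]
        coarse_sizes = pd.Series(coarse).value_counts()
        pmap = {}
        for f in pd.unique(fine):
            counts = pd.Series(coarse[fine == f]).value_counts()
            best = counts.max()
            tied = sorted(
                counts[counts == best].index,
                key=lambda c: (-coarse_sizes[c], str(c)),
            )
            pmap[f] = tied[0]
        parent_maps.append(pmap)
    # relabel upward from the finest level to enforce nesting
    out = [None] * len(arrays)
    out[-1] = arrays[-1]
    for lvl in range(len(arrays) - 2, -1, -1):
        pmap = parent_maps[lvl]
        out[lvl] = np.array([pmap[f] for f in out[lvl + 1]], dtype=object)
    return ClusterTree(out)


def _mean_profiles(gm, tree: ClusterTree, nodes: list) -> dict:
    prof = {}
    for n in nodes:
        prof[n] = np.asarray(gm.lognorm[tree.cells_of(n)].mean(axis=0)).ravel()
    return prof


def count_sibling_markers(
    markers: pd.DataFrame, min_spec: float, p_adj_max: float
) -> pd.Series:
    """Per node: number of vs-siblings genes with specificity > min_spec and
    p_adj < p_adj_max."""
    sib = markers[markers["reference"] == "siblings"]
    ok = sib[(sib["specificity"] > min_spec) & (sib["p_adj"] < p_adj_max)]
    return ok.groupby("node_id").size()


def _pairwise_marker_count(
    gm, idx_a, idx_b, strata, min_spec, p_adj_max, min_pct, min_abs_lfc
) -> int:
    """Genes discriminating a sibling pair in either direction."""
    from atlasforge.markers import _compare

    res = _compare(gm, idx_a, idx_b, strata, min_pct, min_abs_lfc)
    n = int(((np.abs(res["specificity"]) > min_spec) & (res["p_adj"] < p_adj_max)).sum())
    # specificity is asymmetric (pct_in vs pct_out swap); check the reverse too
    rev = _compare(gm, idx_b, idx_a, strata, min_pct, min_abs_lfc)
    n_rev = int(((np.abs(rev["specificity"]) > min_spec) & (rev["p_adj"] < p_adj_max)).sum())
    return max(n, n_rev)


def prune_tree(
    tree: ClusterTree,
    gm,
    strata=None,
    min_markers: int = 10,
    min_spec: float = 1.0,
    p_adj_max: float = 0.05,
    single_pass: bool = False,
    min_pct: float = 0.1,
    min_abs_lfc: float = 0.25,
    mode: str = "pairwise",
) -> ClusterTree:
    """Merge sibling clusters lacking ``min_markers`` discriminative genes
    (specificity > ``min_spec``, p_adj < ``p_adj_max``).

    ``mode="pairwise"`` (default) merges a sibling pair when fewer than
    ``min_markers`` genes distinguish the two clusters from each other —
    over-split twins collapse while genuinely distinct siblings survive.
    ``mode="pooled"`` instead counts each node's markers against all its
    siblings pooled and merges weak nodes into their most similar sibling
    (highest Spearman rho of mean lognorm profiles). Markers are recomputed
    after every merge and the rule iterated to fixpoint unless
    ``single_pass``; node ids are reassigned from the final level sizes.
    """
    from atlasforge.markers import sibling_markers

    if mode not in {"pairwise", "pooled"}:
        raise ValueError("mode must be 'pairwise' or 'pooled'")
    if gm.lognorm is None:
        raise ValueError("lognorm layer required")
    from atlasforge.markers import _as_strata

    strata_arr = _as_strata(gm, strata)
    arrays = [np.array(tree.level_labels(l), dtype=object) for l in range(tree.n_levels)]

    changed = True
    while changed:
        changed = False
        t = ClusterTree(arrays)
        for level in range(1, t.n_levels):
            for par in t.nodes_at(level - 1):
                sibs = t.children_of(par)
                if len(sibs) < 2:
                    continue
                merge_pair = None
                if mode == "pairwise":
                    weakest = None  # (count, a, b)
                    for i, a in enumerate(sorted(sibs)):
                        for b in sorted(sibs)[i + 1 :]:
                            n = _pairwise_marker_count(
                                gm, t.cells_of(a), t.cells_of(b), strata_arr,
                                min_spec, p_adj_max, min_pct, min_abs_lfc,
                            )
                            if n < min_markers and (weakest is None or n < weakest[0]):
                                weakest = (n, a, b)
                    if weakest is not None:
                        merge_pair = (weakest[1], weakest[2])
                        logger.info(
                            "pruning pair %s + %s (%d discriminative genes)",
                            *merge_pair, weakest[0],
                        )
                else:
                    cells_by_node = {s: t.cells_of(s) for s in sibs}
                    mk = sibling_markers(
                        gm, cells_by_node, strata, min_pct=min_pct,
                        min_abs_lfc=min_abs_lfc,
                    )
                    counts = count_sibling_markers(mk, min_spec, p_adj_max)
                    weak = sorted(
                        (s for s in sibs if counts.get(s, 0) < min_markers),
                        key=lambda s: (counts.get(s, 0), str(s)),
                    )
                    if weak:
                        node = weak[0]
                        prof = _mean_profiles(gm, t, sibs)
                        best, best_rho = None, -np.inf
                        for o in sorted(s for s in sibs if s != node):
                            rho = scipy.stats.spearmanr(prof[node], prof[o]).statistic
                            if np.isnan(rho):
                                rho = -1.0
                            if rho > best_rho:
                                best, best_rho = o, rho
                        merge_pair = (node, best)
                        logger.info(
                            "pruning %s into %s (rho=%.3f, %d markers)",
                            node, best, best_rho, counts.get(node, 0),
                        )
                if merge_pair is not None:
                    src, dst = merge_pair
                    merge_mask = arrays[level] == _raw_label(t, arrays, level, src)
                    arrays[level][merge_mask] = _raw_label(t, arrays, level, dst)
                    changed = True
                    break
            if changed:
                break
        if single_pass:
            break
    return ClusterTree(arrays)


def _raw_label(t: ClusterTree, arrays: list, level: int, node_id: str):
    """Raw label value in ``arrays[level]`` corresponding to a node id."""
    cell = t.cells_of(node_id)[0]
    return arrays[level][cell]
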