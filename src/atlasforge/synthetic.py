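"""Seeded generators for every pipeline input, with exported ground truth.

Counts follow a hierarchical negative-binomial model: a balanced cell-type
tree with per-node marker genes, multiplicative per-batch gene effects,
optional doublets, and a condition effect that up-regulates immediate-early
genes (IEGs) in designated nodes. Companion generators produce an ISH voxel
grid with region-specific marker energies, bulk IP-vs-input signatures as
noisy cluster mixtures, and a distorted second modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from atlasforge.data_model import GeneMatrix


@dataclass
class SimConfig:
    """All knobs of the synthetic model; ``seed`` governs every draw."""

    seed: int = 0
    n_genes: int = 300
    n_cells: int = 2000
    tree_depth: int = 3
    branching: int = 3
    markers_per_node: int = 5
    marker_log2fc: float = 3.0
    marker_base_rate: float = 0.04
    nb_dispersion: float = 10.0
    library_mu: float = float(np.log(5000.0))
    library_sigma: float = 0.3
    n_batches: int = 1
    samples_per_batch: int = 1
    n_datasets: int = 1
    batch_sd: float = 0.0
    doublet_rate: float = 0.0
    condition_effect: dict = field(default_factory=dict)  # node id -> IEG log2FC
    fasted_fraction: float = 0.5
    n_iegs: int = 0
    modality_distortion: dict = field(default_factory=dict)  # gene class -> factor
    n_regions: int = 4
    voxels_per_region: int = 5
    voxel_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0, 1]")
        if not 0.0 <= self.fasted_fraction <= 1.0:
            raise ValueError("fasted_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.branching ** self.tree_depth < 2:
            raise ValueError("tree must have at least 2 leaves")

    @property
    def n_leaves(self) -> int:
        return self.branching**self.tree_depth

    @property
    def n_samples(self) -> int:
        return self.n_batches * self.samples_per_batch


@dataclass
class PlantedTree:
    """Balanced node tree with per-node marker gene sets.

    Node ids are slash paths (root ``"R"``, children ``"R/0"``...), so the
    ancestor at depth d is a string prefix.
    """

    depth: int
    branching: int
    nodes: list  # all node ids below root, BFS order
    parent: dict
    children: dict
    markers: dict  # node id -> list of gene ids

    @property
    def leaves(self) -> list:
        return [n for n in self.nodes if n.count("/") == self.depth]

    def ancestors(self, node: str) -> list:
        """Ancestors of ``node`` below root, coarse to fine, including itself."""
        parts = node.split("/")
        return ["/".join(parts[: i + 1]) for i in range(1, len(parts))]

    def ancestor_at_depth(self, leaf: str, depth: int) -> str:
        return "/".join(leaf.split("/")[: depth + 1])


def _gene_ids(cfg: SimConfig) -> np.ndarray:
    return np.array([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)


def ieg_genes(cfg: SimConfig) -> list:
    """The designated IEG panel: the last ``n_iegs`` gene ids (never markers)."""
    return [f"g{i:04d}" for i in range(cfg.n_genes - cfg.n_iegs, cfg.n_genes)]


def simulate_hierarchy(cfg: SimConfig) -> PlantedTree:
    """Balanced tree of ``branching`` ** ``tree_depth`` leaves with disjoint
    marker sets of ``markers_per_node`` genes per node below root."""
    rng = np.random.default_rng(cfg.seed)
    nodes, parent, children = [], {}, {"R": []}
    frontier = ["R"]
    for _depth in range(cfg.tree_depth):
        nxt = []
        for p in frontier:
            for b in range(cfg.branching):
                nid = f"{p}/{b}"
                nodes.append(nid)
                parent[nid] = p
                children.setdefault(p, [])
                children[p].append(nid)
                children[nid] = []
                nxt.append(nid)
        frontier = nxt
    n_marker_genes = len(nodes) * cfg.markers_per_node
    assignable = cfg.n_genes - cfg.n_iegs
    if n_marker_genes > assignable:
        raise ValueError(
            f"{n_marker_genes} marker genes demanded but only {assignable} assignable"
        )
    gene_ids = _gene_ids(cfg)
    pool = rng.permutation(assignable)
    markers = {}
    for i, node in enumerate(nodes):
        block = pool[i * cfg.markers_per_node : (i + 1) * cfg.markers_per_node]
        markers[node] = [str(gene_ids[j]) for j in sorted(block)]
    return PlantedTree(cfg.tree_depth, cfg.branching, nodes, parent, children, markers)


@dataclass
class GroundTruth:
    """Planted labels and effects exported alongside the simulated data."""

    cells: pd.DataFrame  # cell_id, leaf, level_1..level_depth, sample, batch, condition, is_doublet
    node_markers: dict
    tree: PlantedTree
    base_rate: np.ndarray
    batch_effects: np.ndarray  # n_batches x n_genes multiplicative

    def level_labels(self, depth: int) -> np.ndarray:
        return self.cells[f"level_{depth}"].to_numpy()


def _base_rate(cfg: SimConfig, tree: PlantedTree) -> np.ndarray:
    """Per-gene baseline rate: gamma-distributed background, with marker
    genes pinned to ``marker_base_rate`` so their out-of-node expression
    fraction stays modest and the planted fold change is recoverable."""
    rng = np.random.default_rng(cfg.seed + 10)
    base = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_genes) + 0.05
    gene_ids = _gene_ids(cfg)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for genes in tree.markers.values():
        for g in genes:
            base[gpos[g]] = cfg.marker_base_rate
    return base


def _leaf_rates(cfg: SimConfig, tree: PlantedTree, base_rate: np.ndarray) -> pd.DataFrame:
    """Unnormalized expected rate per (leaf, gene), marker boosts applied."""
    gene_ids = _gene_ids(cfg)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    rates = {}
    for leaf in tree.leaves:
        r = base_rate.copy()
        for node in tree.ancestors(leaf):
            idx = [gpos[g] for g in tree.markers[node]]
            r[idx] *= 2.0**cfg.marker_log2fc
        rates[leaf] = r
    return pd.DataFrame(rates, index=gene_ids).T


def simulate_counts(
    cfg: SimConfig, tree: PlantedTree
) -> tuple[GeneMatrix, pd.DataFrame, GroundTruth]:
    """Draw NB counts for ``cfg.n_cells`` cells plus doublets.

    Counts ~ NB(mean = libsize * softmax-style normalized rate, dispersion
    theta = ``nb_dispersion``), with per-(batch, gene) 2^N(0, batch_sd)
    effects and 2^condition_effect IEG boosts in fasted cells of designated
    nodes. Doublets are appended by halving the sum of two random cells.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = _gene_ids(cfg)
    base_rate = _base_rate(cfg, tree)
    leaf_rates = _leaf_rates(cfg, tree, base_rate)

    leaves = tree.leaves
    leaf_of = rng.integers(0, len(leaves), size=cfg.n_cells)
    sample_of = rng.integers(0, cfg.n_samples, size=cfg.n_cells)
    batch_of_sample = np.arange(cfg.n_samples) // cfg.samples_per_batch
    batch_of = batch_of_sample[sample_of]
    condition = np.where(
        rng.random(cfg.n_cells) < cfg.fasted_fraction, "fasted", "fed"
    )
    batch_effects = 2.0 ** rng.normal(0.0, cfg.batch_sd, size=(cfg.n_batches, cfg.n_genes))
    libsize = rng.lognormal(cfg.library_mu, cfg.library_sigma, size=cfg.n_cells)

    iegs = ieg_genes(cfg)
    ieg_idx = np.array([np.where(gene_ids == g)[0][0] for g in iegs], dtype=int)
    effect_nodes = set(cfg.condition_effect)

    rate = leaf_rates.to_numpy()[leaf_of] * batch_effects[batch_of]
    if effect_nodes and len(ieg_idx):
        for i in range(cfg.n_cells):
            if condition[i] != "fasted":
                continue
            path = set(tree.ancestors(leaves[leaf_of[i]]))
            hit = path & effect_nodes
            if hit:
                lfc = max(cfg.condition_effect[n] for n in hit)
                rate[i, ieg_idx] *= 2.0**lfc
    mean = rate / rate.sum(axis=1, keepdims=True) * libsize[:, None]
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))

    n_dbl = int(round(cfg.doublet_rate * cfg.n_cells))
    if n_dbl:
        a = rng.integers(0, cfg.n_cells, size=n_dbl)
        b = rng.integers(0, cfg.n_cells, size=n_dbl)
        dbl = (counts[a] + counts[b] + 1) // 2
        counts = np.vstack([counts, dbl])
        leaf_of = np.concatenate([leaf_of, leaf_of[a]])
        sample_of = np.concatenate([sample_of, sample_of[a]])
        batch_of = np.concatenate([batch_of, batch_of[a]])
        condition = np.concatenate([condition, condition[a]])
    n_total = counts.shape[0]
    is_doublet = np.zeros(n_total, dtype=bool)
    is_doublet[cfg.n_cells :] = True

    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_total)], dtype=object)
    leaf_labels = np.array(leaves, dtype=object)[leaf_of]
    gt = pd.DataFrame({"cell_id": cell_ids, "leaf": leaf_labels})
    for d in range(1, cfg.tree_depth + 1):
        gt[f"level_{d}"] = [tree.ancestor_at_depth(lf, d) for lf in leaf_labels]
    gt["sample"] = np.array([f"s{j}" for j in sample_of], dtype=object)
    gt["batch"] = np.array([f"b{j}" for j in batch_of], dtype=object)
    gt["condition"] = condition
    gt["is_doublet"] = is_doublet

    gm = GeneMatrix(cell_ids, gene_ids, sp.csr_matrix(counts))
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": gt["sample"],
            "dataset_id": np.array(
                [f"d{batch_of_sample[j] % cfg.n_datasets}" for j in sample_of],
                dtype=object,
            ),
            "condition": condition,
            "class_label": gt["level_1"],
            "umi_count": counts.sum(axis=1),
            "mito_fraction": 0.0,
            "is_doublet": is_doublet,
        }
    )
    truth = GroundTruth(gt, dict(tree.markers), tree, base_rate, batch_effects)
    return gm, cells, truth


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: hierarchy + counts in one call."""
    tree = simulate_hierarchy(cfg)
    gm, cells, truth = simulate_counts(cfg, tree)
    return gm, cells, truth


def simulate_voxels(cfg: SimConfig, tree: PlantedTree, region_leaves: list | None = None):
    """ISH-style voxel grid: lognormal baseline probe energies, with the home
    region's leaf markers boosted above every baseline energy.

    Returns ``(VoxelGrid, region_to_leaf)``. With ``voxel_noise_sd = 0`` the
    home markers occupy exactly the top ranks in home voxels.
    """
    from atlasforge.regions import VoxelGrid

    rng = np.random.default_rng(cfg.seed + 2)
    leaves = tree.leaves
    if region_leaves is None:
        if cfg.n_regions > len(leaves):
            raise ValueError("more regions than leaves")
        region_leaves = leaves[: cfg.n_regions]
    gene_ids = _gene_ids(cfg)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    base = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    boost = base.max() / base.min() * 2.0

    rows, voxel_ids, regions = [], [], []
    region_to_leaf = {}
    for r, leaf in enumerate(region_leaves):
        region = f"region_{r}"
        region_to_leaf[region] = leaf
        midx = [gpos[g] for g in tree.markers[leaf]]
        for v in range(cfg.voxels_per_region):
            e = base * np.exp(rng.normal(0.0, cfg.voxel_noise_sd, size=cfg.n_genes))
            e[midx] *= boost
            rows.append(e)
            voxel_ids.append(f"{region}_v{v}")
            regions.append(region)
    energies = pd.DataFrame(np.vstack(rows), index=voxel_ids, columns=gene_ids)
    grid = VoxelGrid(energies, pd.Series(regions, index=voxel_ids, name="region"))
    return grid, region_to_leaf


def simulate_bulk_signature(
    cfg: SimConfig,
    tree: PlantedTree,
    target_nodes: list,
    weights: list,
    lfc_noise_sd: float = 0.0,
    rep_sd: float = 0.25,
    n_rep: int = 3,
) -> pd.DataFrame:
    """Bulk IP-vs-input DE table for a weighted mixture of tree nodes.

    True log2FC compares the mixture's expected expression with the global
    mean over leaves; adjusted p-values come from a ``n_rep`` vs ``n_rep``
    t-test on replicate log-expression with sd ``rep_sd`` (BH-corrected).
    ``rep_sd = 0`` is the noise-free limit (p = 0 wherever log2FC != 0).
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(cfg.seed + 3)
    leaf_rates = _leaf_rates(cfg, tree, _base_rate(cfg, tree))
    norm = leaf_rates.div(leaf_rates.sum(axis=1), axis=0)

    def node_mean(node):
        sub = [lf for lf in tree.leaves if lf == node or lf.startswith(node + "/")]
        return norm.loc[sub].mean(axis=0)

    mix = sum(w * node_mean(n) for n, w in zip(target_nodes, weights))
    global_mean = norm.mean(axis=0)
    lfc_true = np.log2((mix + 1e-12) / (global_mean + 1e-12)).to_numpy()
    lfc_obs = lfc_true + rng.normal(0.0, lfc_noise_sd, size=cfg.n_genes)

    if rep_sd == 0:
        p = np.where(np.abs(lfc_true) > 1e-12, 0.0, 1.0)
    else:
        ip = lfc_true[:, None] + rng.normal(0.0, rep_sd, size=(cfg.n_genes, n_rep))
        inp = rng.normal(0.0, rep_sd, size=(cfg.n_genes, n_rep))
        p = scipy.stats.ttest_ind(ip, inp, axis=1).pvalue
    p_adj = scipy.stats.false_discovery_control(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame(
        {"gene": _gene_ids(cfg), "log2FC": lfc_obs, "p_adj": p_adj}
    )


def simulate_second_modality(
    cfg: SimConfig,
    gm: GeneMatrix,
    gene_class_map: dict,
    resample: bool = True,
) -> GeneMatrix:
    """Resample counts with class-specific multiplicative mean distortion.

    Per-gene factor comes from ``cfg.modality_distortion[gene_class]``
    (default 1.0). With ``resample=True`` new counts are Poisson draws around
    the distorted means; with ``resample=False`` and factor 1.0 the matrix
    passes through unchanged.
    """
    missing = [g for g in gm.gene_ids if g not in gene_class_map]
    if missing:
        raise ValueError(f"gene_class_map misses {len(missing)} genes, e.g. {missing[0]!r}")
    rng = np.random.default_rng(cfg.seed + 4)
    factors = np.array(
        [cfg.modality_distortion.get(gene_class_map[g], 1.0) for g in gm.gene_ids]
    )
    mean = np.asarray(gm.counts.todense(), dtype=float) * factors
    if resample:
        new = rng.poisson(mean)
    else:
        new = np.rint(mean).astype(np.int64)
    return GeneMatrix(gm.cell_ids, gm.gene_ids, sp.csr_matrix(new))
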