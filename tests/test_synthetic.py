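import numpy as np
import pandas as pd
import pytest
import scipy.stats

from atlasforge.data_model import lognormalize
from atlasforge.synthetic import (
    SimConfig,
    ieg_genes,
    simulate_bulk_signature,
    simulate_counts,
    simulate_hierarchy,
    simulate_second_modality,
    simulate_voxels,
)


class TestHierarchy:
    def test_node_counts(self):
        cfg = SimConfig(seed=0, tree_depth=3, branching=3)
        tree = simulate_hierarchy(cfg)
        assert len(tree.leaves) == 27
        assert len(tree.nodes) == 39  # 3 + 9 + 27 below root

    def test_marker_sets_disjoint(self):
        tree = simulate_hierarchy(SimConfig(seed=1))
        seen = set()
        for genes in tree.markers.values():
            assert not (set(genes) & seen)
            seen |= set(genes)

    def test_deterministic(self):
        a = simulate_hierarchy(SimConfig(seed=5))
        b = simulate_hierarchy(SimConfig(seed=5))
        assert a.markers == b.markers and a.nodes == b.nodes

    def test_too_many_markers_errors(self):
        with pytest.raises(ValueError, match="marker"):
            simulate_hierarchy(SimConfig(seed=0, n_genes=30, markers_per_node=10))


class TestCounts:
    def test_no_doublets_at_rate_zero(self, sim):
        _, _, _, _, truth = sim
        assert not truth.cells["is_doublet"].any()

    def test_doublets_appended(self):
        cfg = SimConfig(seed=2, n_cells=200, doublet_rate=0.1)
        tree = simulate_hierarchy(cfg)
        gm, cells, truth = simulate_counts(cfg, tree)
        assert truth.cells["is_doublet"].sum() == 20
        assert gm.n_cells == 220

    def test_marker_pct_separation(self, sim):
        # planted markers: pct_in - pct_out > 0.4 on average in their node
        cfg, tree, gm, _, truth = sim
        gaps = []
        for node, genes in truth.node_markers.items():
            d = node.count("/")
            mask = (truth.cells[f"level_{d}"] == node).to_numpy()
            gidx = gm.gene_index(genes)
            pct_in = np.asarray((gm.counts[mask][:, gidx] > 0).mean(axis=0)).ravel()
            pct_out = np.asarray((gm.counts[~mask][:, gidx] > 0).mean(axis=0)).ravel()
            gaps.extend(pct_in - pct_out)
        assert np.mean(gaps) > 0.4

    def test_batch_sd_zero_uniform_means(self):
        cfg = SimConfig(seed=4, n_cells=1500, n_batches=2, batch_sd=0.0)
        tree = simulate_hierarchy(cfg)
        gm, _, truth = simulate_counts(cfg, tree)
        b = truth.cells["batch"].to_numpy()
        m0 = np.asarray(gm.counts[b == "b0"].mean(axis=0)).ravel()
        m1 = np.asarray(gm.counts[b == "b1"].mean(axis=0)).ravel()
        # identical generating means -> per-gene sample means correlate ~1
        assert np.corrcoef(m0, m1)[0, 1] > 0.98

    def test_deterministic_byte_for_byte(self):
        cfg = SimConfig(seed=9, n_cells=150)
        t = simulate_hierarchy(cfg)
        a, ca, ta = simulate_counts(cfg, t)
        b, cb, tb = simulate_counts(cfg, t)
        assert (a.counts != b.counts).nnz == 0
        pd.testing.assert_frame_equal(ca, cb)
        pd.testing.assert_frame_equal(ta.cells, tb.cells)

    def test_ground_truth_self_consistent(self, sim):
        _, tree, _, _, truth = sim
        for d in (2, 3):
            fine = truth.cells[f"level_{d}"]
            coarse = truth.cells[f"level_{d - 1}"]
            assert all(f.startswith(c + "/") for f, c in zip(fine, coarse))


class TestVoxels:
    def test_noise_free_home_markers_top_ranked(self):
        cfg = SimConfig(
            seed=6, n_genes=100, markers_per_node=10, tree_depth=2, branching=2,
            voxel_noise_sd=0.0,
        )
        tree = simulate_hierarchy(cfg)
        grid, r2l = simulate_voxels(cfg, tree)
        region = "region_0"
        markers = tree.markers[r2l[region]]
        for v in grid.region_voxels(region):
            e = grid.energies.loc[v]
            order = e.sort_values(ascending=False).index[: len(markers)]
            assert set(order) == set(markers)

    def test_deterministic(self):
        cfg = SimConfig(seed=7)
        tree = simulate_hierarchy(cfg)
        a, _ = simulate_voxels(cfg, tree)
        b, _ = simulate_voxels(cfg, tree)
        pd.testing.assert_frame_equal(a.energies, b.energies)

    def test_nonmarker_rank_uniform_across_regions(self):
        cfg = SimConfig(
            seed=8, n_genes=150, tree_depth=2, branching=3, n_regions=2,
            voxels_per_region=250, voxel_noise_sd=0.5,
        )
        tree = simulate_hierarchy(cfg)
        grid, r2l = simulate_voxels(cfg, tree)
        home_markers = set(tree.markers[r2l["region_0"]]) | set(
            tree.markers[r2l["region_1"]]
        )
        probe = next(g for g in grid.energies.columns if g not in home_markers)
        ranks = {}
        for region in ("region_0", "region_1"):
            rs = []
            for v in grid.region_voxels(region):
                e = grid.energies.loc[v]
                rs.append(scipy.stats.rankdata(-e.to_numpy())[list(e.index).index(probe)])
            ranks[region] = rs
        p = scipy.stats.ks_2samp(ranks["region_0"], ranks["region_1"]).pvalue
        assert p > 0.01


class TestBulkSignature:
    def test_noise_free_single_node_markers_lead(self):
        cfg = SimConfig(seed=10)
        tree = simulate_hierarchy(cfg)
        leaf = tree.leaves[0]
        de = simulate_bulk_signature(cfg, tree, [leaf], [1.0], rep_sd=0.0)
        top = de.sort_values("log2FC", ascending=False)["gene"].head(
            cfg.markers_per_node
        )
        assert set(top) == set(tree.markers[leaf])

    def test_mixture_markers_in_top(self):
        cfg = SimConfig(seed=11)
        tree = simulate_hierarchy(cfg)
        a, b = tree.leaves[0], tree.leaves[10]
        de = simulate_bulk_signature(cfg, tree, [a, b], [0.5, 0.5], rep_sd=0.1)
        top = set(
            de.sort_values("log2FC", ascending=False)["gene"].head(
                2 * cfg.markers_per_node
            )
        )
        assert set(tree.markers[a]) <= top and set(tree.markers[b]) <= top

    def test_uniform_mixture_mostly_null(self):
        cfg = SimConfig(seed=12)
        tree = simulate_hierarchy(cfg)
        leaves = tree.leaves
        de = simulate_bulk_signature(
            cfg, tree, leaves, [1.0 / len(leaves)] * len(leaves), rep_sd=0.5
        )
        # true fold changes are all ~0; significance stays near the type-I rate
        assert (de["p_adj"] < 0.05).mean() < 0.1


class TestSecondModality:
    def _class_map(self, cfg, split=0.5):
        genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
        cut = int(len(genes) * split)
        return {g: ("A" if i < cut else "B") for i, g in enumerate(genes)}

    def test_identity_without_resampling(self, sim):
        cfg, _, gm, _, _ = sim
        out = simulate_second_modality(cfg, gm, self._class_map(cfg), resample=False)
        assert (out.counts != gm.counts).nnz == 0

    def test_no_distortion_high_correlation(self):
        cfg = SimConfig(seed=13, n_cells=800)
        tree = simulate_hierarchy(cfg)
        gm, _, truth = simulate_counts(cfg, tree)
        out = simulate_second_modality(cfg, gm, self._class_map(cfg))
        a = np.asarray(gm.counts.mean(axis=0)).ravel()
        b = np.asarray(out.counts.mean(axis=0)).ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_distorted_class_lower_correlation(self):
        cfg = SimConfig(
            seed=14, n_cells=800, modality_distortion={"A": 0.2, "B": 1.0}
        )
        tree = simulate_hierarchy(cfg)
        gm, _, truth = simulate_counts(cfg, tree)
        cmap = self._class_map(cfg)
        out = simulate_second_modality(cfg, gm, cmap)
        lvl = truth.level_labels(3)
        ga = lognormalize(gm)
        gb = lognormalize(out)
        rs = {"A": [], "B": []}
        for j, g in enumerate(gm.gene_ids):
            pa = pd.Series(np.asarray(ga.lognorm[:, j].todense()).ravel()).groupby(lvl).mean()
            pb = pd.Series(np.asarray(gb.lognorm[:, j].todense()).ravel()).groupby(lvl).mean()
            if pa.std() > 0 and pb.std() > 0:
                rs[cmap[g]].append(np.corrcoef(pa, pb)[0, 1])
        assert np.mean(rs["A"]) < np.mean(rs["B"])

    def test_incomplete_class_map_errors(self, sim):
        cfg, _, gm, _, _ = sim
        with pytest.raises(ValueError, match="class_map"):
            simulate_second_modality(cfg, gm, {"g0000": "A"})


def test_ieg_genes_never_markers():
    cfg = SimConfig(seed=15, n_iegs=10)
    tree = simulate_hierarchy(cfg)
    iegs = set(ieg_genes(cfg))
    for genes in tree.markers.values():
        assert not (set(genes) & iegs)
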