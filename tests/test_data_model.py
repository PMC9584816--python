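import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasforge.data_model import (
    FormatError,
    GeneMatrix,
    flag_doublet_clusters,
    flag_multisignature_clusters,
    lognormalize,
    pca_embed,
    qc_filter,
    read_counts,
    select_hvgs,
    write_counts,
)


def toy_matrix(counts, cells=None, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return GeneMatrix(
        cell_ids=cells or [f"c{i}" for i in range(n)],
        gene_ids=genes or [f"g{j}" for j in range(g)],
        counts=sp.csr_matrix(counts),
    )


class TestIO:
    def test_roundtrip_exact(self, tmp_path):
        gm = toy_matrix([[0, 3], [1, 0], [5, 2]])
        write_counts(gm, tmp_path)
        back = read_counts(
            tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv"
        )
        assert list(back.cell_ids) == list(gm.cell_ids)
        assert list(back.gene_ids) == list(gm.gene_ids)
        assert (back.counts != gm.counts).nnz == 0

    def test_sparse_storage(self, tmp_path):
        gm = toy_matrix([[0, 3], [1, 0], [5, 0]])
        assert gm.counts.nnz == 3  # 6 possible entries, 3 stored

    def test_dimension_mismatch(self, tmp_path):
        gm = toy_matrix([[0, 3], [1, 0], [5, 2]])
        write_counts(gm, tmp_path)
        # drop one cell row from the TSV
        cells = pd.read_csv(tmp_path / "cells.tsv", sep="\t").iloc[:2]
        cells.to_csv(tmp_path / "cells.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="cells"):
            read_counts(
                tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv"
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            toy_matrix([[1, 2], [3, 4]], cells=["a", "a"])

    def test_non_integer_rejected(self):
        with pytest.raises(FormatError, match="non-integer"):
            GeneMatrix(["a"], ["g"], sp.csr_matrix(np.array([[1.5]])))


class TestLognormalize:
    def test_zero_total_cell_errors(self):
        gm = toy_matrix([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="qc"):
            lognormalize(gm)

    def test_single_gene_formula(self):
        gm = toy_matrix([[7]])
        ln = lognormalize(gm).lognorm
        assert ln[0, 0] == pytest.approx(np.log1p(10000.0), abs=1e-12)

    def test_two_gene_formula(self):
        gm = toy_matrix([[1, 1]])
        ln = lognormalize(gm).lognorm
        expected = np.log1p(5000.0)  # each gene is half the library
        assert ln[0, 0] == pytest.approx(expected, abs=1e-12)
        assert ln[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_sparsity_support_preserved(self, sim):
        _, _, gm, _, _ = sim
        assert (gm.lognorm != 0).nnz == (gm.counts != 0).nnz
        assert np.all(np.isfinite(gm.lognorm.data))
        assert np.all(gm.lognorm.data >= 0)


def _cells_df(umi, mito):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(umi))],
            "umi_count": umi,
            "mito_fraction": mito,
        }
    )


class TestQcFilter:
    def test_low_umi_removed(self):
        gm = toy_matrix([[999], [1000]])
        cells = _cells_df([999, 1000], [0.0, 0.0])
        kept, kept_cells = qc_filter(gm, cells)
        assert list(kept_cells["cell_id"]) == ["c1"]

    def test_inclusive_boundaries(self):
        gm = toy_matrix([[1000]])
        cells = _cells_df([1000], [0.10])
        kept, kept_cells = qc_filter(gm, cells)
        assert kept.n_cells == 1

    def test_identity_when_all_pass(self):
        gm = toy_matrix([[2000], [3000]])
        cells = _cells_df([2000, 3000], [0.01, 0.02])
        kept, kept_cells = qc_filter(gm, cells)
        assert kept.n_cells == 2
        assert (kept.counts != gm.counts).nnz == 0

    @given(
        min_umi=st.integers(min_value=0, max_value=3000),
        stricter=st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_min_umi(self, min_umi, stricter):
        rng = np.random.default_rng(0)
        umi = rng.integers(1, 3000, size=30)
        gm = toy_matrix(umi[:, None])
        cells = _cells_df(umi, np.zeros(30))
        loose, _ = qc_filter(gm, cells, min_umi=min_umi)
        tight, _ = qc_filter(gm, cells, min_umi=min_umi + stricter)
        assert tight.n_cells <= loose.n_cells


class TestSelectHvgs:
    def test_planted_marker_outranks_housekeeping(self):
        rng = np.random.default_rng(7)
        n = 400
        # housekeeping: uniform Poisson everywhere; marker: same mean overall
        # but concentrated in one quarter of cells
        hk = rng.poisson(2.0, size=n)
        marker = np.zeros(n, dtype=int)
        marker[:100] = rng.poisson(8.0, size=100)
        filler = rng.poisson(2.0, size=(n, 40))
        counts = np.column_stack([hk, marker, filler])
        gm = lognormalize(
            toy_matrix(counts, genes=["hk", "marker"] + [f"f{i}" for i in range(40)])
        )
        hv = select_hvgs(gm, n=gm.n_genes, n_bins=5)
        assert hv.index("marker") < hv.index("hk")

    def test_all_genes_when_n_equals(self, sim):
        _, _, gm, _, _ = sim
        assert set(select_hvgs(gm, n=gm.n_genes)) == set(map(str, gm.gene_ids))

    def test_constant_zero_gene_never_selected(self):
        counts = np.column_stack(
            [np.zeros(50, dtype=int), np.random.default_rng(1).poisson(3, (50, 10))]
        )
        gm = lognormalize(toy_matrix(counts, genes=["zero"] + [f"g{i}" for i in range(10)]))
        assert "zero" not in select_hvgs(gm, n=5)


class TestPcaEmbed:
    def test_low_rank_tail_variance(self):
        rng = np.random.default_rng(0)
        # exactly two distinct cell profiles -> lognorm has rank <= 2
        proto = rng.integers(1, 20, size=(2, 30))
        counts = proto[np.arange(100) % 2]
        gm = lognormalize(toy_matrix(counts))
        emb = pca_embed(gm, [f"g{j}" for j in range(30)], n_pcs=10)
        var = emb.var(axis=0)
        assert var[2:].sum() < 0.05 * var.sum()

    def test_separates_planted_clusters(self):
        from sklearn.metrics import silhouette_score

        from atlasforge.synthetic import SimConfig, simulate_counts, simulate_hierarchy

        cfg = SimConfig(
            seed=21, n_cells=400, n_genes=100, tree_depth=1, branching=2,
            markers_per_node=10,
        )
        tree = simulate_hierarchy(cfg)
        gm, _, truth = simulate_counts(cfg, tree)
        gm = lognormalize(gm)
        emb = pca_embed(gm, select_hvgs(gm, 60), n_pcs=10)
        assert silhouette_score(emb[:, :1], truth.level_labels(1)) > 0.5

    def test_deterministic(self, sim):
        _, _, gm, _, _ = sim
        hv = select_hvgs(gm, 60)
        a = pca_embed(gm, hv, n_pcs=20)
        b = pca_embed(gm, hv, n_pcs=20)
        assert np.array_equal(a, b)

    def test_too_many_pcs_errors(self, sim):
        _, _, gm, _, _ = sim
        with pytest.raises(ValueError):
            pca_embed(gm, select_hvgs(gm, 10), n_pcs=11)


class TestDoubletClusters:
    def _cells(self, flags):
        return pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(len(flags))], "is_doublet": flags}
        )

    def test_above_70pct_flagged(self):
        cells = self._cells([True] * 8 + [False] * 2)
        assert flag_doublet_clusters(cells, ["x"] * 10) == {"x"}

    def test_exactly_70pct_not_flagged(self):
        cells = self._cells([True] * 7 + [False] * 3)
        assert flag_doublet_clusters(cells, ["x"] * 10) == set()

    def test_no_doublets_empty(self):
        cells = self._cells([False] * 10)
        assert flag_doublet_clusters(cells, ["x"] * 5 + ["y"] * 5) == set()

    def test_planted_recovery(self):
        # doublet fraction 0.9 in planted clusters, <=0.05 in pure ones
        rng = np.random.default_rng(5)
        labels, flags = [], []
        for cl, frac in [("dbl1", 0.9), ("dbl2", 0.9), ("pure1", 0.05), ("pure2", 0.0)]:
            n = 100
            labels += [cl] * n
            f = np.zeros(n, dtype=bool)
            f[: int(frac * n)] = True
            flags += list(rng.permutation(f))
        cells = self._cells(flags)
        assert flag_doublet_clusters(cells, labels) == {"dbl1", "dbl2"}

    def test_label_mismatch_errors(self):
        cells = self._cells([False] * 3)
        with pytest.raises(ValueError):
            flag_doublet_clusters(cells, ["x"] * 2)


class TestMultisignatureClusters:
    def _doublet_fixture(self):
        rng = np.random.default_rng(11)
        n = 60
        neuron = np.column_stack(
            [rng.poisson(10, (n, 3)), rng.poisson(0.05, (n, 3)), rng.poisson(2, (n, 4))]
        )
        astro = np.column_stack(
            [rng.poisson(0.05, (n, 3)), rng.poisson(10, (n, 3)), rng.poisson(2, (n, 4))]
        )
        mixed = (neuron + astro + 1) // 2
        counts = np.vstack([neuron, astro, mixed])
        genes = [f"n{i}" for i in range(3)] + [f"a{i}" for i in range(3)] + [
            f"b{i}" for i in range(4)
        ]
        gm = lognormalize(
            toy_matrix(counts, cells=[f"c{i}" for i in range(3 * n)], genes=genes)
        )
        labels = ["neu"] * n + ["ast"] * n + ["dbl"] * n
        sigs = {"neuron": {"n0", "n1", "n2"}, "astro": {"a0", "a1", "a2"}}
        return gm, labels, sigs

    def test_planted_doublet_cluster_flagged(self):
        gm, labels, sigs = self._doublet_fixture()
        assert flag_multisignature_clusters(gm, labels, sigs, 1.0) == {"dbl"}

    def test_pure_clusters_not_flagged(self):
        gm, labels, sigs = self._doublet_fixture()
        flagged = flag_multisignature_clusters(gm, labels, sigs, 1.0)
        assert "neu" not in flagged and "ast" not in flagged

    def test_single_class_always_empty(self):
        gm, labels, sigs = self._doublet_fixture()
        assert flag_multisignature_clusters(
            gm, labels, {"neuron": sigs["neuron"]}, 0.0
        ) == set()

    def test_empty_signature_errors(self):
        gm, labels, _ = self._doublet_fixture()
        with pytest.raises(ValueError):
            flag_multisignature_clusters(gm, labels, {}, 1.0)
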