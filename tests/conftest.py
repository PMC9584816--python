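import numpy as np
import pytest

from atlasforge.data_model import lognormalize
from atlasforge.markers import markers_for_tree
from atlasforge.synthetic import SimConfig, simulate_counts, simulate_hierarchy
from atlasforge.tree import ClusterTree


@pytest.fixture(scope="session")
def sim():
    """Default synthetic dataset: depth-3/branching-3 hierarchy, 2,000 cells."""
    cfg = SimConfig(seed=3, n_cells=2000, n_genes=300)
    tree = simulate_hierarchy(cfg)
    gm, cells, truth = simulate_counts(cfg, tree)
    gm = lognormalize(gm)
    return cfg, tree, gm, cells, truth


@pytest.fixture(scope="session")
def planted_ctree(sim):
    """ClusterTree built directly from the planted labels (levels 1..3)."""
    _, _, _, _, truth = sim
    return ClusterTree([truth.level_labels(d) for d in (1, 2, 3)])


@pytest.fixture(scope="session")
def marker_table(sim, planted_ctree):
    _, _, gm, _, _ = sim
    return markers_for_tree(gm, planted_ctree)


def planted_node_id(truth, ctree, node_sim):
    """Map a planted tree node id to the ClusterTree node id covering it."""
    depth = node_sim.count("/")
    mask = (truth.cells[f"level_{depth}"] == node_sim).to_numpy()
    cell = int(np.flatnonzero(mask)[0])
    return ctree.level_labels(depth - 1)[cell]
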