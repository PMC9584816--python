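"""Rank-based region prediction from ISH voxel probe energies.

Each cluster's high-specificity markers are located among a voxel's
energy-ranked probes; regions whose voxels place those markers near the top
score close to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


@dataclass
class VoxelGrid:
    """Voxel x probe energy matrix with a region label per voxel."""

    energies: pd.DataFrame  # index voxel_id, columns probe (gene) ids
    regions: pd.Series  # index voxel_id -> region label

    def __post_init__(self) -> None:
        if not self.energies.index.equals(self.regions.index):
            raise ValueError("energies and regions indices differ")
        if (self.energies.to_numpy() < 0).any():
            raise ValueError("negative probe energy")
        if self.regions.isna().any() or (self.regions == "").any():
            raise ValueError("empty region label")

    @property
    def voxel_ids(self) -> list:
        return list(self.energies.index)

    def region_voxels(self, region: str) -> list:
        return list(self.regions.index[self.regions == region])


def voxel_probe_ranks(energies: pd.Series, eps: float = 0.0) -> pd.Series:
    """Ranks of expressed probes in one voxel: rank 1 = highest energy,
    midranks on ties; unexpressed probes (energy <= eps) are excluded."""
    expressed = energies[energies > eps]
    if expressed.empty:
        warnings.warn("voxel has no expressed probe; skipped", stacklevel=2)
        return pd.Series(dtype=float)
    ranks = scipy.stats.rankdata(-expressed.to_numpy())
    return pd.Series(ranks, index=expressed.index)


def voxel_enrichment(
    energies: pd.Series, marker_probes, eps: float = 0.0, ascending: bool = False
) -> float:
    """Median marker rank divided by the voxel's expressed-probe count.

    Small values mean markers sit near the top of the energy ranking.
    ``ascending=True`` flips the rank direction (rank 1 = lowest energy).
    """
    ranks = voxel_probe_ranks(energies, eps)
    if ranks.empty:
        return np.nan
    if ascending:
        ranks = len(ranks) + 1 - ranks
    marker_ranks = ranks.reindex([m for m in marker_probes if m in ranks.index]).dropna()
    if marker_ranks.empty:
        return np.nan
    return float(np.median(marker_ranks) / len(ranks))


def region_score(
    marker_probes,
    grid: VoxelGrid,
    region: str,
    top_n: int = 4,
    eps: float = 0.0,
    ascending: bool = False,
) -> float:
    """1 - mean normalized median marker rank over the region's ``top_n``
    most enriched voxels (all voxels if fewer)."""
    marker_probes = [m for m in marker_probes if m in grid.energies.columns]
    if not marker_probes:
        warnings.warn(f"no marker probe available for region {region}", stacklevel=2)
        return 0.0
    enr = []
    for v in grid.region_voxels(region):
        e = voxel_enrichment(grid.energies.loc[v], marker_probes, eps, ascending)
        if np.isfinite(e):
            enr.append(e)
    if not enr:
        return 0.0
    enr = np.sort(np.asarray(enr))[:top_n]
    return float(1.0 - enr.mean())


def node_marker_probes(
    markers: pd.DataFrame, node: str, spec_min: float = 4.0, p_adj_max: float = 0.05
) -> list:
    """Vs-all markers of ``node`` with specificity above ``spec_min``."""
    m = markers[
        (markers["node_id"] == node)
        & (markers["reference"] == "all")
        & (markers["specificity"] > spec_min)
        & (markers["p_adj"] < p_adj_max)
    ]
    return sorted(m["gene"].astype(str))


def predict_regions(
    tree,
    markers: pd.DataFrame,
    grid: VoxelGrid,
    level: int,
    threshold: float = 0.8,
    spec_min: float = 4.0,
    top_n: int = 4,
    origin_priors: dict | None = None,
    dataset_of_cell=None,
    scale_floor: float = 0.25,
    top_k_report: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Score every (node, region) pair at one tree level and assign origins.

    Raw scores are down-scaled by the fraction of the node's cells coming
    from datasets compatible with the region (``origin_priors``: dataset ->
    iterable of compatible regions; absent datasets are compatible with
    all), floored at ``scale_floor``. The argmax region is assigned when its
    adjusted score exceeds ``threshold``; the top ``top_k_report`` regions
    per node are reported.
    """
    origin_priors = origin_priors or {}
    regions = sorted(set(grid.regions))
    rows = []
    assignment: dict = {}
    for node in tree.nodes_at(level):
        probes = node_marker_probes(markers, node, spec_min)
        cells = tree.cells_of(node)
        for region in regions:
            raw = region_score(probes, grid, region, top_n=top_n)
            factor = 1.0
            if origin_priors and dataset_of_cell is not None:
                ds = np.asarray(dataset_of_cell)[cells]
                compat = np.array(
                    [region in origin_priors.get(d, {region}) for d in ds]
                )
                factor = max(scale_floor, float(compat.mean()))
            rows.append(
                {
                    "node_id": node,
                    "region": region,
                    "raw_score": raw,
                    "adjusted_score": raw * factor,
                    "n_markers_used": len(probes),
                }
            )
        node_rows = [r for r in rows if r["node_id"] == node]
        node_rows.sort(key=lambda r: (-r["adjusted_score"], r["region"]))
        best = node_rows[0]
        assignment[node] = best["region"] if best["adjusted_score"] > threshold else None
    table = pd.DataFrame(rows)
    table["rank"] = table.groupby("node_id")["adjusted_score"].rank(
        ascending=False, method="first"
    )
    table = (
        table[table["rank"] <= top_k_report]
        .sort_values(["node_id", "rank"])
        .reset_index(drop=True)
    )
    return table, assignment
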