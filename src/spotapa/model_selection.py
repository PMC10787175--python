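"""Neighbor-count selection for imputation via the comprehensive index.

For each candidate k the usage matrix is imputed, spots are clustered with a
graph-based community method, and the eight validation metrics are computed.
Each metric is Z-scored across the k grid (Davies-Bouldin negated, since
lower is better) and the Z-scores are summed into the comprehensive index;
the k maximizing it wins, smaller k on near-ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .apa_usage import UsageMatrix
from .clustering_metrics import METRIC_DIRECTIONS, MetricPanel, external_metrics, internal_metrics
from .io_formats import GeneSpotMatrix, SpotLayout, ValidationError
from .knn_imputation import ImputationConfig, NeighborRanking, build_ranking, impute, scale_genes

__all__ = ["KSelectionResult", "cluster_spots", "comprehensive_index", "select_k"]

logger = logging.getLogger(__name__)

NEAR_TIE = 1e-9


@dataclass
class KSelectionResult:
    k_grid: list[int]
    panels: list[MetricPanel]
    zsum: np.ndarray
    k_opt: int

    def to_table(self):
        import pandas as pd

        rows = []
        for k, panel, z in zip(self.k_grid, self.panels, self.zsum):
            row = {"k": k, **panel.as_dict(), "zsum": z}
            rows.append(row)
        return pd.DataFrame(rows)


def cluster_spots(u: UsageMatrix, resolution: float = 1.0, *,
                  n_neighbors: int = 20, n_pcs: int = 30, seed: int = 0,
                  fill_missing_zero: bool = False) -> list[int]:
    """Cluster spots from a usage matrix: PCA, SNN graph, Leiden modularity.

    Mirrors the common single-cell recipe (shared-nearest-neighbor graph with
    Jaccard edge weights, RB-configuration modularity at ``resolution``).
    Returns one integer label per spot.
    """
    if u.missing.any() and not fill_missing_zero:
        raise ValidationError("usage matrix must be fully imputed before clustering")
    X = np.where(u.missing, 0.0, u.values).T  # spots x genes
    m = X.shape[0]
    if m < 3:
        raise ValidationError("need at least 3 spots to cluster")
    n_neighbors = min(n_neighbors, m - 1)
    n_pcs = min(n_pcs, m - 1, X.shape[1])
    if n_pcs >= 1 and X.shape[1] > n_pcs:
        X = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    if np.allclose(X, X[0]):  # no structure at all: one community
        return [0] * m

    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    for i in range(m):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)

    graph = ig.Graph(n=m, edges=edges)
    graph.es["weight"] = weights
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=-1,
    )
    return list(part.membership)


def comprehensive_index(panels: Sequence[MetricPanel]) -> np.ndarray:
    """Sum of per-metric Z-scores across the grid; DBI contributes negated.

    Metrics constant across the grid (or undefined anywhere) contribute 0.
    """
    if len(panels) < 2:
        raise ValueError("comprehensive index needs >= 2 panels")
    zsum = np.zeros(len(panels))
    for metric, direction in METRIC_DIRECTIONS.items():
        vals = np.array([getattr(p, metric) for p in panels], dtype=float)
        if not np.all(np.isfinite(vals)):
            continue
        sd = vals.std()  # population sd across the grid
        if sd == 0:
            continue
        z = (vals - vals.mean()) / sd
        zsum += -z if direction == "lower_better" else z
    return zsum


def select_k(u_raw: UsageMatrix, g: GeneSpotMatrix, layout: SpotLayout,
             k_grid: Sequence[int], *, cfg_template: Optional[ImputationConfig] = None,
             resolution: float = 1.0, seed: int = 0,
             ranking: Optional[NeighborRanking] = None) -> KSelectionResult:
    """Impute/cluster/score across a k grid and pick the comprehensive-index argmax."""
    m = u_raw.n_spots
    grid = []
    for k in k_grid:
        if k >= m:
            warnings.warn(f"skipping k={k}: not below spot count {m}")
            continue
        grid.append(int(k))
    if len(grid) < 2:
        raise ValueError("k grid must contain >= 2 usable values")

    if ranking is None:
        g_use = g if g.scaled else scale_genes(g)
        ranking = build_ranking(g_use)

    ref = None
    if layout.layer is not None:
        spot_layer = dict(zip(layout.spot_ids, layout.layer))
        ref = [spot_layer[s] for s in u_raw.spot_ids]
    else:
        logger.warning("no reference labels: comprehensive index uses internal metrics only")

    panels = []
    for k in grid:
        cfg = ImputationConfig(
            k=k,
            max_iter=cfg_template.max_iter if cfg_template else 10,
            fill_residual_zero=cfg_template.fill_residual_zero if cfg_template else True,
        )
        imputed = impute(u_raw, ranking, cfg)
        pred = cluster_spots(imputed, resolution=resolution, seed=seed)
        if ref is not None:
            ext = external_metrics(pred, ref)
        else:
            ext = {"ari": float("nan"), "jaccard": float("nan"),
                   "nmi": float("nan"), "purity": float("nan")}
        X = imputed.values.T
        if len(set(pred)) >= 2:
            internal = internal_metrics(X, pred)
        else:
            internal = {"dbi": float("nan"), "ch": float("nan"),
                        "silhouette": float("nan"), "dunn": float("nan")}
        panels.append(MetricPanel(**ext, **internal))
        logger.info("k=%d panel=%s", k, panels[-1].as_dict())

    zsum = comprehensive_index(panels)
    best = zsum.max()
    # smaller k preferred among near-ties
    k_opt = min(k for k, z in zip(grid, zsum) if z >= best - NEAR_TIE)
    return KSelectionResult(k_grid=grid, panels=panels, zsum=zsum, k_opt=k_opt)
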