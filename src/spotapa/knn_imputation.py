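"""Iterative KNN imputation of sparse usage matrices guided by gene expression.

Spot neighborhoods come from the scaled gene-expression matrix: per-gene
centering/standardization, Euclidean spot-spot distances, and a per-spot
neighbor ranking (nearest first, ties broken by spot index, self excluded).
Missing usage cells are filled by the mean usage of the k nearest spots that
have non-zero, non-missing usage for that gene; rounds repeat synchronously
(each round reads the previous round's matrix) until no cell can be filled or
the iteration cap is hit, after which residual missing cells default to 0.
Observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .apa_usage import UsageMatrix
from .io_formats import GeneSpotMatrix, SpotLayout, ValidationError

__all__ = [
    "NeighborRanking",
    "ImputationConfig",
    "ConfigError",
    "scale_genes",
    "build_ranking",
    "impute",
    "align_usage_to_expression",
    "evaluate_imputation",
]


class ConfigError(ValueError):
    pass


@dataclass
class NeighborRanking:
    """Spot-spot Euclidean distances and per-spot nearest-first neighbor order."""

    spot_ids: list[str]
    distance: np.ndarray  # (m, m) symmetric, zero diagonal
    ranking: np.ndarray   # (m, m-1) int; row i = other spots by ascending distance

    def __post_init__(self) -> None:
        m = len(self.spot_ids)
        if self.distance.shape != (m, m):
            raise ValidationError("distance matrix shape mismatch")
        if self.ranking.shape != (m, m - 1):
            raise ValidationError("ranking matrix shape mismatch")


@dataclass
class ImputationConfig:
    k: int = 10
    max_iter: int = 10
    fill_residual_zero: bool = True

    def validate(self, n_spots: int) -> None:
        if not 1 <= self.k < n_spots:
            raise ConfigError(f"k={self.k} must satisfy 1 <= k < {n_spots} spots")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")


def scale_genes(g: GeneSpotMatrix, ddof: int = 1) -> GeneSpotMatrix:
    """Center each gene row to mean 0 and scale to unit standard deviation.

    Uses the sample (n-1) standard deviation. Zero-variance rows become
    all-zero rows rather than NaN.
    """
    if g.scaled:
        raise ValidationError("matrix is already scaled")
    centered = g.values - g.values.mean(axis=1, keepdims=True)
    sd = g.values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return GeneSpotMatrix(
        gene_ids=list(g.gene_ids), values=scaled, spot_ids=list(g.spot_ids),
        scaled=True,
    )


def build_ranking(g_scaled: GeneSpotMatrix) -> NeighborRanking:
    """Euclidean spot-spot distances over all genes, plus nearest-first ranking."""
    if not g_scaled.scaled:
        raise ValidationError("build_ranking requires a scaled matrix")
    m = g_scaled.n_spots
    if m < 2:
        raise ValidationError("need at least 2 spots")
    D = squareform(pdist(g_scaled.values.T, metric="euclidean"))
    # stable argsort breaks distance ties by ascending spot index
    order = np.argsort(D, axis=1, kind="stable")
    ranking = np.empty((m, m - 1), dtype=np.intp)
    for i in range(m):
        row = order[i]
        ranking[i] = row[row != i]
    return NeighborRanking(spot_ids=list(g_scaled.spot_ids), distance=D, ranking=ranking)


def align_usage_to_expression(u: UsageMatrix, g: GeneSpotMatrix) -> UsageMatrix:
    """Zero-fill usage rows for genes absent from the expression matrix.

    Those cells become observed zeros and are not imputed afterwards.
    """
    known = set(g.gene_ids)
    out = u.copy()
    for i, gene in enumerate(u.gene_ids):
        if gene not in known:
            out.values[i, :] = 0.0
            out.missing[i, :] = False
    return out


def impute(r: UsageMatrix, ranking: NeighborRanking,
           cfg: Optional[ImputationConfig] = None) -> UsageMatrix:
    """Fill missing cells of ``r`` by iterative neighbor averaging."""
    cfg = cfg or ImputationConfig()
    if list(r.spot_ids) != list(ranking.spot_ids):
        raise ValidationError("usage matrix and ranking must share spot ids")
    cfg.validate(r.n_spots)

    neighbors = ranking.ranking[:, : cfg.k]  # (m, k) nearest spots per spot
    values = r.values.copy()
    missing = r.missing.copy()

    for _ in range(cfg.max_iter):
        if not missing.any():
            break
        donor_ok = (~missing) & (values != 0)          # (h, m)
        nb_vals = values[:, neighbors]                 # (h, m, k)
        nb_ok = donor_ok[:, neighbors]                 # (h, m, k)
        L = nb_ok.sum(axis=2)                          # (h, m)
        sums = (nb_vals * nb_ok).sum(axis=2)
        fillable = missing & (L > 0)
        if not fillable.any():
            break
        new_vals = np.where(fillable, sums / np.maximum(L, 1), values)
        values = np.where(missing, new_vals, values)   # observed cells untouched
        missing = missing & ~fillable

    if cfg.fill_residual_zero:
        values = np.where(missing, 0.0, values)
        missing = np.zeros_like(missing)

    return UsageMatrix(
        gene_ids=list(r.gene_ids), spot_ids=list(r.spot_ids),
        values=values, missing=missing, usage_type=r.usage_type,
    )


def within_layer_correlations(u: UsageMatrix, layout: SpotLayout) -> dict[str, float]:
    """Median pairwise spot Pearson correlation within each reference layer."""
    if layout.layer is None:
        raise ValidationError("layout has no layer labels")
    spot_layer = dict(zip(layout.spot_ids, layout.layer))
    out: dict[str, float] = {}
    for layer in sorted(set(layout.layer)):
        cols = [j for j, s in enumerate(u.spot_ids) if spot_layer.get(s) == layer]
        if len(cols) < 2:
            continue
        sub = u.values[:, cols]
        corr = np.corrcoef(sub.T)
        iu = np.triu_indices(len(cols), k=1)
        vals = corr[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[layer] = float(np.median(vals))
    return out


def evaluate_imputation(raw: UsageMatrix, imputed: UsageMatrix, layout: SpotLayout,
                        seed: int = 0, resolution: float = 1.0) -> dict:
    """Eight-metric clustering panel for raw vs imputed matrices plus
    within-layer spot correlations."""
    from .clustering_metrics import MetricPanel, external_metrics, internal_metrics
    from .model_selection import cluster_spots

    if layout.layer is None:
        raise ValidationError("layout has no layer labels")
    spot_layer = dict(zip(layout.spot_ids, layout.layer))
    ref = [spot_layer[s] for s in imputed.spot_ids]

    def panel(u: UsageMatrix) -> MetricPanel:
        X = np.where(u.missing, 0.0, u.values).T  # spots x genes
        pred = cluster_spots(u, resolution=resolution, seed=seed, fill_missing_zero=True)
        ext = external_metrics(pred, ref)
        if len(set(pred)) < 2:
            internal = {"dbi": float("nan"), "ch": float("nan"),
                        "silhouette": float("nan"), "dunn": float("nan")}
        else:
            internal = internal_metrics(X, pred)
        return MetricPanel(**ext, **internal)

    return {
        "raw": panel(raw),
        "imputed": panel(imputed),
        "layer_correlations_raw": within_layer_correlations(raw, layout),
        "layer_correlations_imputed": within_layer_correlations(imputed, layout),
    }
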