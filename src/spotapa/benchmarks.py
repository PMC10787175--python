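"""Robustness benchmarks on simulated data: masking curves and recovery metrics.

For a seeded simulated dataset with planted layer patterns, these helpers
mask spots and/or entries, impute, and compare raw vs imputed matrices on
RMSE against the planted truth, layer-clustering ARI, planted-gene detection
sensitivity, and mean Moran's I of the pattern genes. The CLI ``benchmark``
subcommand and the acceptance suite are thin wrappers over this module.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .apa_usage import UsageMatrix, compute_rud
from .clustering_metrics import external_metrics, knn_weights, morans_i
from .io_formats import SpotLayout
from .knn_imputation import ImputationConfig, NeighborRanking, build_ranking, impute, scale_genes
from .model_selection import cluster_spots
from .spatial_apa import detect_lsapa
from .synthetic_data import (
    SimulatedDataset, SimulationSpec, mask_entries, mask_spots, sensitivity, simulate,
)

__all__ = [
    "make_benchmark_dataset",
    "truth_matrix",
    "rmse_vs_truth",
    "masking_comparison",
    "dropout_benchmark",
    "mean_pattern_moran",
]


def make_benchmark_dataset(seed: int = 0, n_spots: int = 200, n_layers: int = 2,
                           n_genes: int = 80, n_apa_genes: int = 30,
                           n_pattern_genes: int = 10, depth: float = 20.0,
                           delta: float = 0.4,
                           geometry: str = "stripes") -> SimulatedDataset:
    spec = SimulationSpec(
        n_spots=n_spots,
        layer_geometry=geometry,
        layer_proportions=tuple([1.0 / n_layers] * n_layers),
        n_genes=n_genes, n_apa_genes=n_apa_genes,
        n_pattern_genes=n_pattern_genes, depth=depth, seed=seed,
    )
    from .synthetic_data import default_patterns

    spec.planted_patterns = default_patterns(spec, delta=delta)
    return simulate(spec)


def truth_matrix(ds: SimulatedDataset, u: UsageMatrix) -> np.ndarray:
    """Planted per-cell RUD aligned to ``u`` (gene x spot)."""
    spot_layer = dict(zip(ds.layout.spot_ids, ds.layout.layer))
    truth_lookup = {
        (row["gene"], row["layer"]): row["true_rud"]
        for _, row in ds.truth.iterrows()
    }
    out = np.full((u.n_genes, u.n_spots), np.nan)
    for i, gene in enumerate(u.gene_ids):
        for j, spot in enumerate(u.spot_ids):
            key = (gene, spot_layer[spot])
            if key in truth_lookup:
                out[i, j] = truth_lookup[key]
    return out


def rmse_vs_truth(u: UsageMatrix, truth: np.ndarray,
                  observed_only: bool = False) -> float:
    """RMSE of usage values against planted truth.

    ``observed_only`` excludes missing cells (the raw-matrix convention);
    otherwise all cells with defined truth contribute.
    """
    mask = np.isfinite(truth)
    if observed_only:
        mask &= ~u.missing
    diffs = u.values[mask] - truth[mask]
    return float(np.sqrt(np.mean(diffs ** 2)))


def _labels_for(u: UsageMatrix, layout: SpotLayout) -> list[str]:
    spot_layer = dict(zip(layout.spot_ids, layout.layer))
    return [spot_layer[s] for s in u.spot_ids]


def mean_pattern_moran(u: UsageMatrix, layout: SpotLayout,
                       pattern_genes: set[str]) -> float:
    """Mean Moran's I (no permutations) over the planted pattern genes."""
    layout = layout.subset(u.spot_ids)
    W = knn_weights(layout, k=min(6, u.n_spots - 1))
    vals = []
    for i, gene in enumerate(u.gene_ids):
        if gene not in pattern_genes:
            continue
        row = np.where(u.missing[i], 0.0, u.values[i])
        if np.ptp(row) == 0:
            continue
        vals.append(morans_i(row, layout, weights=W, n_perm=0)["I"])
    return float(np.mean(vals)) if vals else float("nan")


def _detected_genes(u: UsageMatrix, labels: Sequence[str]) -> set[str]:
    results = detect_lsapa(u, labels)
    return {r.gene_id for r in results}


def masking_comparison(ds: SimulatedDataset, spot_frac: float, entry_frac: float,
                       k: int = 10, seed: int = 0, resolution: float = 1.0,
                       ranking: Optional[NeighborRanking] = None) -> dict:
    """Mask, impute, and compare raw vs imputed on one masking condition."""
    u_full = compute_rud(ds.pa)
    if spot_frac > 0:
        u_masked, _ = mask_spots(u_full, ds.layout, spot_frac, seed=seed)
    else:
        u_masked = u_full.copy()
    if entry_frac > 0:
        u_masked = mask_entries(u_masked, entry_frac, seed=seed + 1)

    if ranking is None:
        ranking = build_ranking(scale_genes(ds.g))
    imputed = impute(u_masked, ranking, ImputationConfig(k=k))

    truth = truth_matrix(ds, u_full)
    labels = _labels_for(u_full, ds.layout)
    pattern = ds.pattern_genes

    raw_for_clustering = cluster_spots(u_masked, resolution=resolution,
                                       seed=seed, fill_missing_zero=True)
    imp_clusters = cluster_spots(imputed, resolution=resolution, seed=seed)

    raw_filled = u_masked.copy()
    raw_filled.values = np.where(raw_filled.missing, 0.0, raw_filled.values)
    raw_filled.missing = np.zeros_like(raw_filled.missing)

    return {
        "spot_frac": spot_frac,
        "entry_frac": entry_frac,
        "k": k,
        "dropout_rate": u_masked.dropout_rate,
        "rmse_raw": rmse_vs_truth(u_masked, truth, observed_only=True),
        "rmse_imputed": rmse_vs_truth(imputed, truth),
        "ari_raw": external_metrics(raw_for_clustering, labels)["ari"],
        "ari_imputed": external_metrics(imp_clusters, labels)["ari"],
        "sensitivity_raw": sensitivity(pattern, _detected_genes(raw_filled, labels)),
        "sensitivity_imputed": sensitivity(pattern, _detected_genes(imputed, labels)),
        "moran_raw": mean_pattern_moran(u_masked, ds.layout, pattern),
        "moran_imputed": mean_pattern_moran(imputed, ds.layout, pattern),
    }


def dropout_benchmark(seed: int = 0, n_spots: int = 150,
                      spot_fracs: Sequence[float] = (0.0, 0.3, 0.5),
                      entry_fracs: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
                      k: int = 10) -> pd.DataFrame:
    """Masking grid: spot-level fractions crossed with extra entry-level fractions."""
    ds = make_benchmark_dataset(seed=seed, n_spots=n_spots)
    ranking = build_ranking(scale_genes(ds.g))
    rows = []
    for sf in spot_fracs:
        for ef in entry_fracs:
            rows.append(masking_comparison(ds, sf, ef, k=k, seed=seed,
                                           ranking=ranking))
    return pd.DataFrame(rows)
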