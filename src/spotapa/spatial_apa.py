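"""Detection of genes with spatial APA dynamics.

Three categories are covered:

* DEAPA — differential usage between two spot groups (two-sided Wilcoxon
  rank-sum, adjusted p < 0.05 and |log2 fold change| > 0.5 by default);
* LSAPA — one layer against all remaining spots, run per layer;
* SVAPA — globally spatially variable usage; the built-in detector is a
  Moran's I permutation test with Benjamini-Hochberg adjustment, and results
  from external count-based detectors can be imported through a unified TSV
  interface (``usage_to_counts`` prepares their input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .apa_usage import UsageMatrix
from .clustering_metrics import morans_i
from .io_formats import FormatError, GeneSpotMatrix, SpotLayout, ValidationError

__all__ = [
    "SpatialAPAResult",
    "detect_deapa",
    "detect_lsapa",
    "usage_to_counts",
    "detect_svapa_builtin",
    "import_svapa",
    "combine_gene_sets",
    "results_to_table",
]

LOG2FC_PSEUDOCOUNT = 0.01


@dataclass
class SpatialAPAResult:
    gene_id: str
    category: str  # DEAPA | LSAPA | SVAPA
    contrast: str
    statistic: float
    p_raw: float
    p_adj: float
    log2fc: Optional[float] = None
    moran_i: Optional[float] = None


def _require_imputed(u: UsageMatrix) -> None:
    if u.missing.any():
        raise ValidationError("usage matrix contains missing values; impute first")


def _rank_sum_contrast(u: UsageMatrix, mask_a: np.ndarray, mask_b: np.ndarray,
                       contrast: str, category: str, p_thresh: float,
                       lfc_thresh: float, adjust: str,
                       eps: float) -> list[SpatialAPAResult]:
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError(f"contrast {contrast}: each group needs >= 2 spots")
    a = u.values[:, mask_a]
    b = u.values[:, mask_b]
    stats = np.zeros(u.n_genes)
    p_raw = np.ones(u.n_genes)
    for i in range(u.n_genes):
        if np.ptp(np.concatenate([a[i], b[i]])) == 0:
            stats[i], p_raw[i] = 0.0, 1.0
            continue
        res = mannwhitneyu(a[i], b[i], alternative="two-sided", method="auto")
        stats[i], p_raw[i] = float(res.statistic), float(res.pvalue)
    if adjust == "bonferroni":
        p_adj = np.minimum(p_raw * u.n_genes, 1.0)
    elif adjust == "bh":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    log2fc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))

    results = [
        SpatialAPAResult(
            gene_id=u.gene_ids[i], category=category, contrast=contrast,
            statistic=stats[i], p_raw=float(p_raw[i]), p_adj=float(p_adj[i]),
            log2fc=float(log2fc[i]),
        )
        for i in range(u.n_genes)
        if p_adj[i] < p_thresh and abs(log2fc[i]) > lfc_thresh
    ]
    results.sort(key=lambda r: (r.p_adj, r.gene_id))
    return results


def detect_deapa(u: UsageMatrix, labels: Sequence, group_a, group_b,
                 p_thresh: float = 0.05, lfc_thresh: float = 0.5,
                 adjust: str = "bonferroni",
                 eps: float = LOG2FC_PSEUDOCOUNT) -> list[SpatialAPAResult]:
    """Differential APA usage between two labeled spot groups."""
    _require_imputed(u)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != u.n_spots:
        raise ValidationError("labels length does not match spot count")
    mask_a = labels == group_a
    mask_b = labels == group_b
    return _rank_sum_contrast(
        u, mask_a, mask_b, f"{group_a}_vs_{group_b}", "DEAPA",
        p_thresh, lfc_thresh, adjust, eps,
    )


def detect_lsapa(u: UsageMatrix, labels: Sequence,
                 p_thresh: float = 0.05, lfc_thresh: float = 0.5,
                 adjust: str = "bonferroni",
                 eps: float = LOG2FC_PSEUDOCOUNT) -> list[SpatialAPAResult]:
    """Layer-specific APA usage: each layer versus all remaining spots."""
    _require_imputed(u)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != u.n_spots:
        raise ValidationError("labels length does not match spot count")
    out: list[SpatialAPAResult] = []
    for layer in sorted(set(labels), key=str):
        mask_a = labels == layer
        mask_b = ~mask_a
        out.extend(_rank_sum_contrast(
            u, mask_a, mask_b, f"{layer}_vs_rest", "LSAPA",
            p_thresh, lfc_thresh, adjust, eps,
        ))
    return out


def usage_to_counts(u: UsageMatrix, base10_scale: float = 1.0) -> GeneSpotMatrix:
    """Map usage values in [0, 1] to small pseudo-counts for count-based detectors.

    RUD mode: value v -> round(10^v), mapping [0, 1] onto {1..10}. Intronic
    mode: round(2^(c*v)) with c = log2(10) so both modes share the {1..10}
    range. Monotone by construction.
    """
    _require_imputed(u)
    if u.usage_type == "RUD":
        counts = np.round(np.power(10.0, u.values * base10_scale))
    else:
        c = np.log2(10.0)
        counts = np.round(np.power(2.0, c * u.values * base10_scale))
    return GeneSpotMatrix(
        gene_ids=list(u.gene_ids), values=counts, spot_ids=list(u.spot_ids),
    )


def detect_svapa_builtin(u: UsageMatrix, layout: SpotLayout, *,
                         n_perm: int = 199, seed: int = 0,
                         fdr: float = 0.05, knn_k: int = 6) -> list[SpatialAPAResult]:
    """Spatially variable APA usage via per-gene Moran's I permutation tests."""
    import warnings

    _require_imputed(u)
    layout = layout.subset(u.spot_ids)
    from .clustering_metrics import knn_weights

    W = knn_weights(layout, k=min(knn_k, u.n_spots - 1))
    stats, p_raw, genes = [], [], []
    for i, gene in enumerate(u.gene_ids):
        vals = u.values[i]
        if np.ptp(vals) == 0:
            warnings.warn(f"gene {gene}: zero variance, skipped")
            continue
        res = morans_i(vals, layout, weights=W, n_perm=n_perm, seed=seed + i)
        genes.append(gene)
        stats.append(res["I"])
        p_raw.append(res["p_perm"])
    if not genes:
        return []
    p_adj = multipletests(np.asarray(p_raw), method="fdr_bh")[1]
    results = [
        SpatialAPAResult(
            gene_id=g, category="SVAPA", contrast="global",
            statistic=s, p_raw=float(p), p_adj=float(pa), moran_i=s,
        )
        for g, s, p, pa in zip(genes, stats, p_raw, p_adj)
        if pa < fdr
    ]
    results.sort(key=lambda r: (r.p_adj, r.gene_id))
    return results


def import_svapa(path, fdr: float = 0.05) -> list[SpatialAPAResult]:
    """Import SVAPA results produced by an external detector.

    Expects a TSV with a ``gene`` column and ``p_adj`` and/or ``p_raw``; when
    only raw p-values are given they are BH-adjusted on import.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError("SVAPA import requires a 'gene' column")
    if "p_adj" not in df.columns and "p_raw" not in df.columns:
        raise FormatError("SVAPA import requires a 'p_adj' or 'p_raw' column")
    if df.empty:
        return []
    if "p_adj" in df.columns:
        p_adj = df["p_adj"].to_numpy(float)
        p_raw = df["p_raw"].to_numpy(float) if "p_raw" in df.columns else p_adj
    else:
        p_raw = df["p_raw"].to_numpy(float)
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    stat = df["statistic"].to_numpy(float) if "statistic" in df.columns else np.full(len(df), np.nan)
    results = [
        SpatialAPAResult(
            gene_id=str(g), category="SVAPA", contrast="global(imported)",
            statistic=float(s), p_raw=float(p), p_adj=float(pa),
        )
        for g, s, p, pa in zip(df["gene"], stat, p_raw, p_adj)
        if pa < fdr
    ]
    results.sort(key=lambda r: (r.p_adj, r.gene_id))
    return results


def combine_gene_sets(deapa: Sequence[SpatialAPAResult],
                      lsapa: Sequence[SpatialAPAResult],
                      svapa: Sequence[SpatialAPAResult]) -> pd.DataFrame:
    """Non-redundant union of the three gene sets with membership flags."""
    sets = {
        "DEAPA": {r.gene_id for r in deapa},
        "LSAPA": {r.gene_id for r in lsapa},
        "SVAPA": {r.gene_id for r in svapa},
    }
    genes = sorted(set().union(*sets.values()))
    return pd.DataFrame({
        "gene": genes,
        **{cat: [g in members for g in genes] for cat, members in sets.items()},
    })


def results_to_table(results: Sequence[SpatialAPAResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": r.gene_id, "category": r.category, "contrast": r.contrast,
            "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "log2fc": r.log2fc, "moran_i": r.moran_i,
        }
        for r in results
    ])
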