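"""Clustering-validation metrics and Moran's I, implemented from first principles.

External metrics (ARI, pairwise Jaccard, NMI, purity) compare a predicted
labeling with a reference; internal metrics (DBI, CH, silhouette, Dunn) score
a labeling against feature geometry alone. Each is written directly from its
textbook definition so tests can pit it against independent brute-force
oracles. Moran's I uses configurable spatial weights with a permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import SpotLayout

__all__ = [
    "MetricPanel",
    "METRIC_DIRECTIONS",
    "external_metrics",
    "internal_metrics",
    "morans_i",
    "knn_weights",
    "inverse_distance_weights",
]

# higher_better for all metrics except DBI
METRIC_DIRECTIONS = {
    "ari": "higher_better",
    "jaccard": "higher_better",
    "nmi": "higher_better",
    "purity": "higher_better",
    "dbi": "lower_better",
    "ch": "higher_better",
    "silhouette": "higher_better",
    "dunn": "higher_better",
}


@dataclass
class MetricPanel:
    ari: float
    jaccard: float
    nmi: float
    purity: float
    dbi: float
    ch: float
    silhouette: float
    dunn: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_DIRECTIONS}


def _as_codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    return codes


def _contingency(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    table = np.zeros((pred.max() + 1, ref.max() + 1), dtype=np.int64)
    np.add.at(table, (pred, ref), 1)
    return table


def external_metrics(pred: Sequence, ref: Sequence) -> dict[str, float]:
    """ARI, pairwise Jaccard, NMI (arithmetic-mean normalization), purity."""
    if len(pred) != len(ref):
        raise ValueError(f"label length mismatch: {len(pred)} vs {len(ref)}")
    p = _as_codes(pred)
    r = _as_codes(ref)
    n = len(p)
    table = _contingency(p, r)
    a = table.sum(axis=1)  # predicted cluster sizes
    b = table.sum(axis=0)  # reference cluster sizes

    def c2(x):
        return x * (x - 1) // 2

    sum_nij = int(c2(table).sum())
    sum_a = int(c2(a).sum())
    sum_b = int(c2(b).sum())
    total = c2(n)

    # pair counting: TP = co-clustered in both, FP = in pred only, FN = in ref only
    tp = sum_nij
    fp = sum_a - tp
    fn = sum_b - tp
    jaccard = tp / (tp + fp + fn) if (tp + fp + fn) > 0 else 1.0

    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    ari = 1.0 if max_index == expected else (tp - expected) / (max_index - expected)

    with np.errstate(divide="ignore", invalid="ignore"):
        pa = a[a > 0] / n
        pb = b[b > 0] / n
        h_pred = float(-(pa * np.log(pa)).sum())
        h_ref = float(-(pb * np.log(pb)).sum())
        pij = table / n
        outer = np.outer(a, b) / (n * n)
        nz = pij > 0
        mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    denom = (h_pred + h_ref) / 2.0
    nmi = 1.0 if denom == 0 else mi / denom
    nmi = float(np.clip(nmi, 0.0, 1.0))

    purity = float(table.max(axis=1).sum() / n)

    return {"ari": float(ari), "jaccard": float(jaccard), "nmi": nmi, "purity": purity}


def internal_metrics(X: np.ndarray, labels: Sequence) -> dict[str, float]:
    """DBI, CH, mean silhouette, and Dunn index for one labeling of X."""
    X = np.asarray(X, dtype=float)
    codes = _as_codes(labels)
    clusters = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
    k = len(clusters)
    n = X.shape[0]
    if k < 2:
        raise ValueError("internal metrics are undefined for a single cluster")
    if any(len(c) == 0 for c in clusters):
        raise ValueError("empty cluster")

    centroids = np.vstack([X[idx].mean(axis=0) for idx in clusters])
    # mean within-cluster distance to centroid (DBI scatter)
    sigma = np.array([
        np.linalg.norm(X[idx] - centroids[c], axis=1).mean()
        for c, idx in enumerate(clusters)
    ])
    cdist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)

    # Davies-Bouldin
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j and cdist[i, j] > 0:
                ratios[i, j] = (sigma[i] + sigma[j]) / cdist[i, j]
    dbi = float(ratios.max(axis=1).mean())

    # Calinski-Harabasz
    overall = X.mean(axis=0)
    between = sum(len(idx) * np.sum((centroids[c] - overall) ** 2)
                  for c, idx in enumerate(clusters))
    within = sum(np.sum((X[idx] - centroids[c]) ** 2) for c, idx in enumerate(clusters))
    ch = float((between / (k - 1)) / (within / (n - k))) if within > 0 else float("inf")

    # silhouette
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    sil = np.zeros(n)
    for i in range(n):
        own = clusters[codes[i]]
        if len(own) == 1:
            sil[i] = 0.0
            continue
        a_i = D[i, own].sum() / (len(own) - 1)
        b_i = min(D[i, idx].mean() for c, idx in enumerate(clusters) if c != codes[i])
        sil[i] = 0.0 if max(a_i, b_i) == 0 else (b_i - a_i) / max(a_i, b_i)
    silhouette = float(sil.mean())

    # Dunn: min inter-cluster single-linkage distance / max intra-cluster diameter
    min_inter = min(
        D[np.ix_(clusters[i], clusters[j])].min()
        for i in range(k) for j in range(i + 1, k)
    )
    max_diam = max(
        D[np.ix_(idx, idx)].max() for idx in clusters
    )
    dunn = float("inf") if max_diam == 0 else float(min_inter / max_diam)

    return {"dbi": dbi, "ch": ch, "silhouette": silhouette, "dunn": dunn}


def knn_weights(layout: SpotLayout, k: int = 6) -> np.ndarray:
    """Binary k-nearest-neighbor spatial weights (not symmetrized)."""
    xy = layout.coords
    n = len(layout.spot_ids)
    if k >= n:
        raise ValueError(f"k={k} must be < number of spots ({n})")
    D = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        W[i, order[i, :k]] = 1.0
    return W


def inverse_distance_weights(layout: SpotLayout) -> np.ndarray:
    xy = layout.coords
    D = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    W[~np.isfinite(W)] = 0.0
    return W


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    n = len(z)
    s0 = W.sum()
    return float(n / s0 * (z @ W @ z) / (z @ z))


def morans_i(values: Sequence[float], layout: SpotLayout,
             weights: Optional[np.ndarray] = None, *,
             weight_scheme: str = "knn", knn_k: int = 6,
             n_perm: int = 999, seed: int = 0) -> dict[str, float]:
    """Moran's I with a permutation p-value ((b + 1) / (n_perm + 1), one-sided).

    Default weights are binary 6-nearest-neighbor, matching the roughly
    hexagonal spot arrays; pass ``weight_scheme="inverse_distance"`` or an
    explicit ``weights`` matrix to override.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 spots")
    if n != len(layout.spot_ids):
        raise ValueError("values length does not match layout")
    z = values - values.mean()
    if np.allclose(z, 0):
        raise ValueError("Moran's I is undefined for zero-variance values")
    if weights is None:
        if weight_scheme == "knn":
            weights = knn_weights(layout, k=min(knn_k, n - 1))
        elif weight_scheme == "inverse_distance":
            weights = inverse_distance_weights(layout)
        else:
            raise ValueError(f"unknown weight scheme {weight_scheme!r}")

    i_obs = _moran_stat(z, weights)
    if n_perm <= 0:
        return {"I": i_obs, "p_perm": float("nan")}
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if _moran_stat(zp, weights) >= i_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return {"I": i_obs, "p_perm": float(p)}
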