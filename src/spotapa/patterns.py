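"""Spatial usage patterns: k-means over gene usage profiles, representative genes.

Genes from the combined spatial-APA set are clustered in spot-space
(multi-restart k-means, best inertia kept); each group's centroid is its mean
per-spot usage profile. Representatives are members whose Pearson correlation
with the centroid passes r > 0.5 and p < 0.05 by default; groups are ranked
for presentation by a layer-contrast score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .apa_usage import UsageMatrix
from .io_formats import ValidationError

__all__ = ["PatternSet", "cluster_patterns", "select_representatives", "rank_patterns"]


@dataclass
class PatternSet:
    n_groups: int
    gene_ids: list[str]
    assignments: np.ndarray          # group index per gene
    centroids: np.ndarray            # (n_groups, n_spots)
    spot_ids: list[str]
    selected: list[int] = field(default_factory=list)
    representatives: Optional[pd.DataFrame] = None  # gene, group, r, p, selected

    def members(self, group: int) -> list[str]:
        return [g for g, a in zip(self.gene_ids, self.assignments) if a == group]


def cluster_patterns(u: UsageMatrix, genes: Sequence[str], n_groups: int = 10,
                     seed: int = 0, n_start: int = 1000,
                     max_iter: int = 10_000) -> PatternSet:
    """K-means on gene usage profiles (genes as points in spot-space)."""
    if u.missing.any():
        raise ValidationError("usage matrix must be fully imputed")
    gene_idx = {g: i for i, g in enumerate(u.gene_ids)}
    unknown = [g for g in genes if g not in gene_idx]
    if unknown:
        raise ValidationError(f"genes absent from usage matrix: {unknown[:5]}")
    if len(genes) < n_groups:
        raise ValidationError(
            f"{len(genes)} genes cannot form {n_groups} groups"
        )
    X = u.values[[gene_idx[g] for g in genes], :]
    n_distinct = len(np.unique(X, axis=0))
    eff_groups = min(n_groups, n_distinct)
    km = KMeans(
        n_clusters=eff_groups, n_init=n_start, max_iter=max_iter,
        random_state=seed,
    ).fit(X)
    return PatternSet(
        n_groups=eff_groups,
        gene_ids=list(genes),
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        spot_ids=list(u.spot_ids),
    )


def select_representatives(ps: PatternSet, u: UsageMatrix,
                           r_thresh: float = 0.5,
                           p_thresh: float = 0.05) -> PatternSet:
    """Flag genes correlating with their group centroid (Pearson r and t-test p).

    Singleton groups correlate trivially with their own centroid (r = 1); such
    rows carry ``singleton = True`` so they can be discounted.
    """
    gene_idx = {g: i for i, g in enumerate(u.gene_ids)}
    sizes = np.bincount(ps.assignments, minlength=ps.n_groups)
    rows = []
    for gene, grp in zip(ps.gene_ids, ps.assignments):
        profile = u.values[gene_idx[gene]]
        centroid = ps.centroids[grp]
        if np.std(profile) == 0 or np.std(centroid) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(profile, centroid)
        singleton = sizes[grp] == 1
        if singleton:
            r, p = 1.0, 0.0
        rows.append({
            "gene": gene, "group": int(grp), "r": float(r), "p": float(p),
            "singleton": bool(singleton),
            "selected": bool(r > r_thresh and p < p_thresh),
        })
    reps = pd.DataFrame(rows).sort_values(
        ["group", "r"], ascending=[True, False]
    ).reset_index(drop=True)
    ps.representatives = reps
    return ps


def rank_patterns(ps: PatternSet, labels: Sequence, q: int = 5) -> PatternSet:
    """Rank groups by layer contrast of their centroid; mark the top ``q`` selected.

    Score = variance of the centroid's layer-wise means divided by the mean
    within-layer variance (plus a small floor to keep it finite).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(ps.spot_ids):
        raise ValidationError("labels length does not match spot count")
    layers = sorted(set(labels), key=str)
    scores = []
    for grp in range(ps.n_groups):
        centroid = ps.centroids[grp]
        layer_means = np.array([centroid[labels == lay].mean() for lay in layers])
        within = np.mean([
            centroid[labels == lay].var() for lay in layers
        ])
        score = layer_means.var() / (within + 1e-12)
        scores.append(score)
    order = np.argsort(scores, kind="stable")[::-1]
    ps.selected = [int(g) for g in order[: min(q, ps.n_groups)]]
    return ps
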