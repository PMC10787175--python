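"""Simulated spot-barcoded datasets with planted layers, APA patterns, and dropout.

Spots sit on a 2-D grid partitioned into layers (stripes or concentric
rings). Gene totals are negative-binomial; layer-marker genes get a
layer-dependent mean so that expression-based spot distances recover the
layers. Each APA gene carries two (optionally more) 3' UTR poly(A) sites and
its per-spot gene total is split binomially with distal probability equal to
the layer's planted RUD — keeping expression and usage statistically
separable. Masking/subsampling helpers mirror the robustness experiment
designs (spot dropout stratified by layer, extra entry-level dropout, spot
subsampling), and small set utilities compute detection sensitivity and
multi-replicate silver standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .apa_usage import UsageMatrix
from .io_formats import GeneSpotMatrix, PolyASiteMatrix, SpotLayout, ValidationError

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate",
    "mask_spots",
    "mask_entries",
    "subsample_spots",
    "sensitivity",
    "silver_standard",
]


@dataclass
class SimulationSpec:
    n_spots: int = 200
    layer_geometry: str = "stripes"  # stripes | concentric_rings
    layer_proportions: Sequence[float] = (0.5, 0.5)
    n_genes: int = 100
    n_apa_genes: int = 30
    n_pattern_genes: int = 10  # APA genes with layer-dependent RUD
    planted_patterns: Optional[dict[str, dict[str, float]]] = None
    flat_rud: float = 0.5
    depth: float = 20.0
    dropout_spot_frac: float = 0.0
    dropout_cell_frac: float = 0.0
    nb_dispersion: float = 2.0  # NB size parameter; larger = closer to Poisson
    marker_fold: float = 3.0
    utr_sites_per_gene: int = 2
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.layer_proportions) - 1.0) > 1e-9:
            raise ValidationError("layer proportions must sum to 1")
        if not 0 <= self.dropout_spot_frac < 1 or not 0 <= self.dropout_cell_frac < 1:
            raise ValidationError("dropout fractions must lie in [0, 1)")
        if self.n_pattern_genes > self.n_apa_genes:
            raise ValidationError("n_pattern_genes cannot exceed n_apa_genes")
        if self.utr_sites_per_gene < 2:
            raise ValidationError("APA genes need >= 2 UTR sites")
        n_layers = len(self.layer_proportions)
        if min(self._layer_sizes()) < 1:
            raise ValidationError("a layer would receive 0 spots")
        if self.planted_patterns is not None:
            for gene, per_layer in self.planted_patterns.items():
                for v in per_layer.values():
                    if not 0 <= v <= 1:
                        raise ValidationError(f"true RUD out of [0,1] for {gene}")

    def _layer_sizes(self) -> list[int]:
        cum = np.floor(np.cumsum(self.layer_proportions) * self.n_spots + 0.5).astype(int)
        cum[-1] = self.n_spots
        sizes = np.diff(np.concatenate([[0], cum]))
        return sizes.tolist()


@dataclass
class SimulatedDataset:
    pa: PolyASiteMatrix
    g: GeneSpotMatrix
    layout: SpotLayout
    truth: pd.DataFrame  # gene, layer, true_rud, pattern_flag

    @property
    def pattern_genes(self) -> set[str]:
        return set(self.truth.loc[self.truth["pattern_flag"], "gene"])


def _child_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, hash(stage) % (2**31)]))


def _place_spots(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    side = int(np.ceil(np.sqrt(spec.n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    x = xs.ravel()[: spec.n_spots].astype(float)
    y = ys.ravel()[: spec.n_spots].astype(float)
    if spec.layer_geometry == "stripes":
        key = x + 1e-6 * y
    elif spec.layer_geometry == "concentric_rings":
        cx, cy = x.mean(), y.mean()
        key = np.hypot(x - cx, y - cy)
    else:
        raise ValidationError(f"unknown layer geometry {spec.layer_geometry!r}")
    order = np.argsort(key, kind="stable")
    layer_names = [f"L{i+1}" for i in range(len(spec.layer_proportions))]
    labels = np.empty(spec.n_spots, dtype=object)
    start = 0
    for name, size in zip(layer_names, spec._layer_sizes()):
        labels[order[start:start + size]] = name
        start += size
    return x, y, labels.tolist()


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # NB parametrized by mean and size: p = size/(size+mean)
    mean = np.maximum(mean, 1e-12)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def default_patterns(spec: SimulationSpec, delta: float = 0.4,
                     base: float = 0.3) -> dict[str, dict[str, float]]:
    """Planted per-layer RUDs: pattern gene g is elevated in layer g mod n_layers."""
    layer_names = [f"L{i+1}" for i in range(len(spec.layer_proportions))]
    patterns = {}
    for i in range(spec.n_pattern_genes):
        gene = f"apa{i+1}"
        hot = layer_names[i % len(layer_names)]
        patterns[gene] = {
            lay: min(base + delta, 1.0) if lay == hot else base for lay in layer_names
        }
    return patterns


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a full dataset (site counts, expression, layout, truth table)."""
    spec.validate()
    x, y, labels = _place_spots(spec)
    layer_names = [f"L{i+1}" for i in range(len(spec.layer_proportions))]
    spot_ids = [f"s{i+1}" for i in range(spec.n_spots)]
    layout = SpotLayout(spot_ids=spot_ids, x=x, y=y, layer=labels)
    labels_arr = np.asarray(labels, dtype=object)

    apa_genes = [f"apa{i+1}" for i in range(spec.n_apa_genes)]
    other_genes = [f"bg{i+1}" for i in range(spec.n_genes - spec.n_apa_genes)]
    genes = apa_genes + other_genes

    patterns = spec.planted_patterns
    if patterns is None:
        patterns = default_patterns(spec)

    rng_counts = _child_rng(spec.seed, "counts")

    # gene totals: markers among background genes carry layer structure
    means = np.full((len(genes), spec.n_spots), spec.depth, dtype=float)
    for j, gene in enumerate(other_genes):
        hot = layer_names[j % len(layer_names)]
        row = len(apa_genes) + j
        means[row, labels_arr == hot] *= spec.marker_fold
    totals = _nb_counts(rng_counts, means, spec.nb_dispersion)

    # per-APA-gene binomial split into UTR sites; distal prob = planted RUD
    site_rows, site_ids, counts_rows = [], [], []
    truth_rows = []
    n_sites = spec.utr_sites_per_gene
    for gi, gene in enumerate(apa_genes):
        per_layer = patterns.get(gene)
        is_pattern = per_layer is not None
        if per_layer is None:
            per_layer = {lay: spec.flat_rud for lay in layer_names}
        p_distal = np.array([per_layer[lab] for lab in labels_arr], dtype=float)
        gene_tot = totals[gi]
        distal = rng_counts.binomial(gene_tot, p_distal)
        rest = gene_tot - distal
        # remaining reads spread over the proximal site(s)
        if n_sites == 2:
            proximal_parts = [rest]
        else:
            proximal_parts = []
            remaining = rest.copy()
            for s in range(n_sites - 2):
                drawn = rng_counts.binomial(remaining, 1.0 / (n_sites - 1 - s))
                proximal_parts.append(drawn)
                remaining = remaining - drawn
            proximal_parts.append(remaining)
        base_coord = 10_000 * (gi + 1)
        for s, row in enumerate(proximal_parts):
            site_ids.append(f"{gene}.p{s+1}")
            site_rows.append({"site_id": f"{gene}.p{s+1}", "chrom": "chr1",
                              "strand": "+", "coord": base_coord + 100 + 10 * s,
                              "gene": gene, "region": "3UTR"})
            counts_rows.append(row)
        site_ids.append(f"{gene}.d")
        site_rows.append({"site_id": f"{gene}.d", "chrom": "chr1", "strand": "+",
                          "coord": base_coord + 500, "gene": gene, "region": "3UTR"})
        counts_rows.append(distal)
        for lay in layer_names:
            truth_rows.append({"gene": gene, "layer": lay,
                               "true_rud": per_layer[lay],
                               "pattern_flag": is_pattern})

    counts = np.vstack(counts_rows).astype(np.int64)

    # cell-level dropout: zero out APA gene totals in random cells
    if spec.dropout_cell_frac > 0:
        rng_drop = _child_rng(spec.seed, "cell_dropout")
        drop = rng_drop.random((spec.n_apa_genes, spec.n_spots)) < spec.dropout_cell_frac
        for gi in range(spec.n_apa_genes):
            rows = [i for i, sid in enumerate(site_ids) if site_rows[i]["gene"] == apa_genes[gi]]
            counts[np.ix_(rows, np.flatnonzero(drop[gi]))] = 0

    # spot-level dropout: all genes of randomly chosen spots (layer-stratified)
    if spec.dropout_spot_frac > 0:
        rng_spot = _child_rng(spec.seed, "spot_dropout")
        dropped = _stratified_pick(labels_arr, spec.dropout_spot_frac, rng_spot)
        counts[:, dropped] = 0
        totals[:, dropped] = 0

    # expression matrix: APA gene totals from sites + background genes
    g_values = np.vstack([counts_to_gene_totals(counts, site_rows, apa_genes),
                          totals[len(apa_genes):]])
    g = GeneSpotMatrix(gene_ids=genes, values=g_values.astype(float), spot_ids=spot_ids)

    pa = PolyASiteMatrix(
        site_ids=site_ids, counts=counts,
        sites=pd.DataFrame(site_rows), spot_ids=spot_ids,
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(pa=pa, g=g, layout=layout, truth=truth)


def counts_to_gene_totals(counts: np.ndarray, site_rows: list[dict],
                          genes: list[str]) -> np.ndarray:
    out = np.zeros((len(genes), counts.shape[1]), dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for row, meta in zip(counts, site_rows):
        out[gene_pos[meta["gene"]]] += row
    return out


def _stratified_pick(labels: np.ndarray, frac: float,
                     rng: np.random.Generator) -> np.ndarray:
    picked = []
    for lay in sorted(set(labels), key=str):
        members = np.flatnonzero(labels == lay)
        n_pick = int(np.floor(frac * len(members)))
        if len(members) - n_pick < 2:
            raise ValidationError(
                f"masking {frac:.0%} leaves < 2 observed spots in layer {lay}"
            )
        picked.extend(rng.choice(members, size=n_pick, replace=False))
    return np.asarray(sorted(picked), dtype=int)


def mask_spots(u: UsageMatrix, layout: SpotLayout, frac: float,
               seed: int = 0) -> tuple[UsageMatrix, list[str]]:
    """Mask all genes of a layer-stratified random spot fraction.

    Returns the masked matrix and the masked spot ids.
    """
    if not 0 <= frac <= 0.9:
        raise ValidationError("spot-masking fraction must lie in [0, 0.9]")
    if layout.layer is None:
        raise ValidationError("layout needs layer labels for stratified masking")
    if frac == 0:
        return u.copy(), []
    spot_layer = dict(zip(layout.spot_ids, layout.layer))
    labels = np.asarray([spot_layer[s] for s in u.spot_ids], dtype=object)
    rng = np.random.default_rng(seed)
    dropped = _stratified_pick(labels, frac, rng)
    out = u.copy()
    out.missing[:, dropped] = True
    out.values[:, dropped] = 0.0
    return out, [u.spot_ids[i] for i in dropped]


def mask_entries(u: UsageMatrix, frac: float, seed: int = 0) -> UsageMatrix:
    """Set an extra fraction of currently observed entries to missing."""
    if not 0 <= frac <= 0.5:
        raise ValidationError("entry-masking fraction must lie in [0, 0.5]")
    out = u.copy()
    if frac == 0:
        return out
    observed = np.argwhere(~u.missing)
    n_mask = int(np.floor(frac * len(observed)))
    rng = np.random.default_rng(seed)
    chosen = observed[rng.choice(len(observed), size=n_mask, replace=False)]
    out.missing[chosen[:, 0], chosen[:, 1]] = True
    out.values[chosen[:, 0], chosen[:, 1]] = 0.0
    return out


def subsample_spots(ds: SimulatedDataset, frac: float, seed: int = 0) -> SimulatedDataset:
    """Layer-stratified spot subsample across all matrices and the layout."""
    if not 0 < frac <= 1:
        raise ValidationError("subsample fraction must lie in (0, 1]")
    labels = np.asarray(ds.layout.layer, dtype=object)
    rng = np.random.default_rng(seed)
    kept = []
    for lay in sorted(set(labels), key=str):
        members = np.flatnonzero(labels == lay)
        n_keep = max(1, int(np.floor(frac * len(members))))
        kept.extend(rng.choice(members, size=n_keep, replace=False))
    kept = sorted(kept)
    if len(kept) == 0:
        raise ValidationError("subsample left no spots")
    spot_ids = [ds.layout.spot_ids[i] for i in kept]
    pa = PolyASiteMatrix(
        site_ids=list(ds.pa.site_ids), counts=ds.pa.counts[:, kept],
        sites=ds.pa.sites.copy(), spot_ids=spot_ids,
    )
    g = GeneSpotMatrix(
        gene_ids=list(ds.g.gene_ids), values=ds.g.values[:, kept],
        spot_ids=spot_ids, scaled=ds.g.scaled,
    )
    return SimulatedDataset(pa=pa, g=g, layout=ds.layout.subset(spot_ids),
                            truth=ds.truth.copy())


def sensitivity(reference_genes: set[str], detected: set[str]) -> float:
    """TP / (TP + FN) against a reference gene set."""
    reference_genes = set(reference_genes)
    if not reference_genes:
        raise ValidationError("reference gene set is empty")
    tp = len(reference_genes & set(detected))
    return tp / len(reference_genes)


def silver_standard(replicate_results: Sequence[set[str]],
                    min_support: int = 2) -> set[str]:
    """Genes detected in at least ``min_support`` replicate result sets."""
    if len(replicate_results) < 2:
        raise ValidationError("need >= 2 replicate result sets")
    from collections import Counter

    support = Counter()
    for s in replicate_results:
        support.update(set(s))
    return {g for g, c in support.items() if c >= min_support}
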