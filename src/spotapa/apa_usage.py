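"""Per-gene, per-spot APA usage from annotated poly(A)-site counts.

Two usage indices are supported:

* RUD — for 3' UTR APA genes with >= 2 sites in the 3' UTR (extended 3' UTR
  sites are pooled with annotated ones), the distal-site count divided by the
  summed 3' UTR site counts of the gene in that spot.
* intronic ratio — after site-level support filters, the highest per-spot
  fraction of a gene's reads attributed to any one intronic site.

Cells whose denominator is zero are dropouts: recorded in the missing mask,
never conflated with a usage of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import EmptyResultError, GeneSpotMatrix, PolyASiteMatrix, ValidationError

__all__ = ["UsageMatrix", "compute_rud", "compute_intronic_ratio", "gene_level_counts"]

UTR_REGIONS = ("3UTR", "extended3UTR")


@dataclass
class UsageMatrix:
    """Gene x spot usage values in [0, 1] with an explicit missing mask."""

    gene_ids: list[str]
    spot_ids: list[str]
    values: np.ndarray
    missing: np.ndarray
    usage_type: str = "RUD"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.gene_ids), len(self.spot_ids))
        if self.values.shape != shape or self.missing.shape != shape:
            raise ValidationError("values/missing shape does not match ids")
        obs = self.values[~self.missing]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValidationError("observed usage values must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def dropout_rate(self) -> float:
        return float(self.missing.mean()) if self.missing.size else 0.0

    def copy(self) -> "UsageMatrix":
        return UsageMatrix(
            gene_ids=list(self.gene_ids), spot_ids=list(self.spot_ids),
            values=self.values.copy(), missing=self.missing.copy(),
            usage_type=self.usage_type,
        )

    def subset_spots(self, spot_ids: Sequence[str]) -> "UsageMatrix":
        idx = {s: i for i, s in enumerate(self.spot_ids)}
        order = [idx[s] for s in spot_ids]
        return UsageMatrix(
            gene_ids=list(self.gene_ids), spot_ids=list(spot_ids),
            values=self.values[:, order], missing=self.missing[:, order],
            usage_type=self.usage_type,
        )


def _require_annotation(pa: PolyASiteMatrix) -> pd.DataFrame:
    sites = pa.sites
    if "gene" not in sites.columns or "region" not in sites.columns:
        raise ValidationError("sites are not annotated (missing gene/region columns)")
    return sites


def _distal_index(rows: pd.DataFrame) -> int:
    """Positional index (into pa rows) of the strand-aware farthest 3' UTR site."""
    strand = rows["strand"].iloc[0]
    coords = rows["coord"].to_numpy()
    pos = int(np.argmax(coords)) if strand == "+" else int(np.argmin(coords))
    return int(rows.index[pos])


def compute_rud(pa: PolyASiteMatrix) -> UsageMatrix:
    """Relative usage of the distal poly(A) site per eligible gene and spot.

    Eligible genes have at least two sites in the (extended) 3' UTR. The
    distal site is the one farthest from the start codon in transcription
    direction. Spots where no 3' UTR site of the gene is expressed are
    dropouts.
    """
    sites = _require_annotation(pa).reset_index(drop=True)
    utr = sites[sites["region"].isin(UTR_REGIONS) & sites["gene"].notna()]

    gene_ids, values, missing = [], [], []
    for gene, rows in utr.groupby("gene", sort=True):
        if len(rows) < 2:
            continue
        idx = rows.index.to_numpy()
        denom = pa.counts[idx, :].sum(axis=0).astype(float)
        distal = pa.counts[_distal_index(rows), :].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rud = np.where(denom > 0, distal / np.where(denom > 0, denom, 1.0), 0.0)
        gene_ids.append(str(gene))
        values.append(rud)
        missing.append(denom == 0)
    if not gene_ids:
        raise EmptyResultError("no gene has >= 2 sites in the 3' UTR")
    return UsageMatrix(
        gene_ids=gene_ids, spot_ids=list(pa.spot_ids),
        values=np.vstack(values), missing=np.vstack(missing), usage_type="RUD",
    )


def compute_intronic_ratio(pa: PolyASiteMatrix, min_reads: int = 3,
                           min_spots: int = 3) -> UsageMatrix:
    """Highest intronic-site read fraction per gene and spot.

    Sites must be supported by ``min_reads`` total reads and be non-zero in
    ``min_spots`` spots; surviving genes need >= 2 sites of which >= 1 is
    intronic. Denominators are summed over surviving sites of the gene.
    """
    sites = _require_annotation(pa).reset_index(drop=True)
    totals = pa.counts.sum(axis=1)
    presence = (pa.counts > 0).sum(axis=1)
    keep = (totals >= min_reads) & (presence >= min_spots)
    surviving = sites[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]
    surviving = surviving[surviving["gene"].notna()]

    gene_ids, values, missing = [], [], []
    for gene, rows in surviving.groupby("gene", sort=True):
        intronic = rows[rows["region"] == "intron"]
        if len(rows) < 2 or intronic.empty:
            continue
        denom = pa.counts[rows.index.to_numpy(), :].sum(axis=0).astype(float)
        intr_counts = pa.counts[intronic.index.to_numpy(), :].astype(float)
        best = intr_counts.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(denom > 0, best / np.where(denom > 0, denom, 1.0), 0.0)
        gene_ids.append(str(gene))
        values.append(ratio)
        missing.append(denom == 0)
    if not gene_ids:
        raise EmptyResultError("no gene passes the intronic APA filters")
    return UsageMatrix(
        gene_ids=gene_ids, spot_ids=list(pa.spot_ids),
        values=np.vstack(values), missing=np.vstack(missing),
        usage_type="intronic_ratio",
    )


def gene_level_counts(pa: PolyASiteMatrix) -> GeneSpotMatrix:
    """Sum site counts per gene; a stand-in when no expression matrix is supplied."""
    sites = _require_annotation(pa).reset_index(drop=True)
    assigned = sites[sites["gene"].notna()]
    gene_ids, rows = [], []
    for gene, grp in assigned.groupby("gene", sort=True):
        gene_ids.append(str(gene))
        rows.append(pa.counts[grp.index.to_numpy(), :].sum(axis=0))
    values = np.vstack(rows) if rows else np.zeros((0, pa.n_spots))
    return GeneSpotMatrix(gene_ids=gene_ids, values=values, spot_ids=list(pa.spot_ids))
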