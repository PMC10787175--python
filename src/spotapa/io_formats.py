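"""Readers/writers for on-disk artifacts: count matrices, spot layouts, usage matrices.

All other modules operate on the in-memory domain types defined here; files are
parsed and validated once at the boundary. Counts are exchanged as Matrix Market
plus sidecar TSVs or as plain dense TSV; usage matrices and layouts are TSV.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "PolyASiteMatrix",
    "GeneSpotMatrix",
    "SpotLayout",
    "FormatError",
    "ValidationError",
    "EmptyResultError",
    "read_polya_matrix",
    "read_spot_layout",
    "read_gene_matrix",
    "filter_low_count_spots",
    "write_usage_matrix",
    "read_usage_matrix",
    "write_polya_matrix",
]

MISSING_TOKEN = "NA"

VALID_REGIONS = frozenset(
    {"3UTR", "extended3UTR", "intron", "CDS", "exon", "intergenic", "unassigned"}
)


class FormatError(ValueError):
    """Raised when a file's structure does not match the expected format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


class EmptyResultError(ValueError):
    """Raised when a filter removes everything."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class PolyASiteMatrix:
    """Poly(A)-site x spot count matrix plus per-site metadata.

    ``sites`` is a DataFrame indexed like ``site_ids`` with columns
    chrom, strand, coord, gene, region.
    """

    site_ids: list[str]
    counts: np.ndarray  # (n_sites, n_spots) non-negative integers
    sites: pd.DataFrame
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.site_ids), len(self.spot_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.spot_ids)} spots"
            )
        _check_unique(self.site_ids, "site ids")
        _check_unique(self.spot_ids, "spot ids")
        if len(self.sites) != len(self.site_ids):
            raise ValidationError(
                f"sites table has {len(self.sites)} rows for {len(self.site_ids)} sites"
            )
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at site {i}, spot {j}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                i, j = np.argwhere(self.counts != np.round(self.counts))[0]
                raise ValidationError(f"non-integer count at site {i}, spot {j}")
            self.counts = self.counts.astype(np.int64)
        bad = set(self.sites["strand"]) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand values: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class GeneSpotMatrix:
    """Gene x spot numeric matrix (raw counts or scaled values)."""

    gene_ids: list[str]
    values: np.ndarray
    spot_ids: list[str]
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.spot_ids, "spot ids")
        if not self.scaled and self.values.size and self.values.min() < 0:
            raise ValidationError("unscaled matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class SpotLayout:
    """Spot identifiers with 2-D array coordinates and optional layer labels."""

    spot_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    layer: Optional[list[str]] = None

    def __post_init__(self) -> None:
        _check_unique(self.spot_ids, "spot ids")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.spot_ids)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValidationError("coordinate arrays must match spot count")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValidationError("missing coordinate")
        if self.layer is not None:
            if len(self.layer) != n:
                raise ValidationError("layer labels must match spot count")
            if any(lab is None or str(lab) == "" for lab in self.layer):
                raise ValidationError("empty layer label")

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, spot_ids: Sequence[str]) -> "SpotLayout":
        idx = {s: i for i, s in enumerate(self.spot_ids)}
        order = [idx[s] for s in spot_ids]
        return SpotLayout(
            spot_ids=list(spot_ids),
            x=self.x[order],
            y=self.y[order],
            layer=[self.layer[i] for i in order] if self.layer is not None else None,
        )


def _read_count_matrix(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".mtx":
        m = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(m):
            m = m.toarray()
        return np.asarray(m)
    df = pd.read_csv(path, sep="\t", header=None)
    # tolerate a header row / index column of labels
    if df.dtypes.apply(lambda d: d == object).any():
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy()


def read_polya_matrix(matrix_path, sites_path, spots_path) -> PolyASiteMatrix:
    """Read a site x spot count matrix plus site/spot metadata sidecars.

    ``matrix_path`` may be Matrix Market (.mtx) or dense TSV. The sites TSV
    must have columns site_id, chrom, strand, coord and optionally gene,
    region; row order defines matrix row order. The spots TSV needs a
    spot_id (or id) column defining column order.
    """
    counts = _read_count_matrix(Path(matrix_path))
    sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
    spots = pd.read_csv(spots_path, sep="\t")
    if counts.shape[0] != len(sites):
        raise FormatError(
            f"matrix has {counts.shape[0]} rows but sites file has {len(sites)} (axis: sites)"
        )
    if counts.shape[1] != len(spots):
        raise FormatError(
            f"matrix has {counts.shape[1]} columns but spots file has {len(spots)} (axis: spots)"
        )
    for col in ("site_id", "chrom", "strand", "coord"):
        if col not in sites.columns:
            raise FormatError(f"sites file lacks required column {col!r}")
    if "gene" not in sites.columns:
        sites["gene"] = None
    if "region" not in sites.columns:
        sites["region"] = "unassigned"
    bad_regions = set(sites["region"].dropna()) - VALID_REGIONS
    if bad_regions:
        raise ValidationError(f"unknown region labels: {sorted(bad_regions)}")
    spot_col = "spot_id" if "spot_id" in spots.columns else "id"
    if spot_col not in spots.columns:
        raise FormatError("spots file lacks a spot_id/id column")
    return PolyASiteMatrix(
        site_ids=sites["site_id"].astype(str).tolist(),
        counts=counts,
        sites=sites.reset_index(drop=True),
        spot_ids=spots[spot_col].astype(str).tolist(),
    )


def write_polya_matrix(pa: PolyASiteMatrix, matrix_path, sites_path, spots_path) -> None:
    """Write counts as Matrix Market (or TSV when the path ends in .tsv)."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(pa.counts))
    else:
        pd.DataFrame(pa.counts).to_csv(matrix_path, sep="\t", header=False, index=False)
    pa.sites.to_csv(sites_path, sep="\t", index=False)
    pd.DataFrame({"spot_id": pa.spot_ids}).to_csv(spots_path, sep="\t", index=False)


def read_spot_layout(path) -> SpotLayout:
    """Read a spot layout TSV with columns id (or spot_id), x, y and optional layer."""
    df = pd.read_csv(path, sep="\t")
    id_col = "id" if "id" in df.columns else "spot_id"
    for col in (id_col, "x", "y"):
        if col not in df.columns:
            raise FormatError(f"layout file lacks required column {col!r}")
    if df[["x", "y"]].isna().any().any():
        raise ValidationError("missing coordinate in layout file")
    layer = None
    if "layer" in df.columns:
        layer = df["layer"].astype(str).tolist()
    return SpotLayout(
        spot_ids=df[id_col].astype(str).tolist(),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        layer=layer,
    )


def write_spot_layout(layout: SpotLayout, path) -> None:
    df = pd.DataFrame({"id": layout.spot_ids, "x": layout.x, "y": layout.y})
    if layout.layer is not None:
        df["layer"] = layout.layer
    df.to_csv(path, sep="\t", index=False)


def read_gene_matrix(matrix_path, genes_path=None, spots_path=None) -> GeneSpotMatrix:
    """Read a gene x spot count matrix.

    Either a labelled TSV (first column gene ids, header spot ids) or an .mtx
    file with genes/spots sidecar TSVs (single id column each).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or spots_path is None:
            raise FormatError("mtx gene matrix requires genes and spots sidecars")
        values = _read_count_matrix(matrix_path)
        genes = pd.read_csv(genes_path, sep="\t").iloc[:, 0].astype(str).tolist()
        spots = pd.read_csv(spots_path, sep="\t").iloc[:, 0].astype(str).tolist()
        if values.shape[0] != len(genes):
            raise FormatError("matrix rows do not match genes sidecar (axis: genes)")
        if values.shape[1] != len(spots):
            raise FormatError("matrix columns do not match spots sidecar (axis: spots)")
        return GeneSpotMatrix(gene_ids=genes, values=values, spot_ids=spots)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return GeneSpotMatrix(
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(float),
        spot_ids=[str(s) for s in df.columns],
    )


def write_gene_matrix(g: GeneSpotMatrix, path) -> None:
    pd.DataFrame(g.values, index=g.gene_ids, columns=g.spot_ids).to_csv(path, sep="\t")


def filter_low_count_spots(g: GeneSpotMatrix, min_total: int = 10) -> GeneSpotMatrix:
    """Drop spots whose total count is below ``min_total`` (kept when >= min_total)."""
    if g.scaled:
        raise ValidationError("filter_low_count_spots requires an unscaled matrix")
    totals = g.values.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise EmptyResultError(f"no spot has total count >= {min_total}")
    return GeneSpotMatrix(
        gene_ids=list(g.gene_ids),
        values=g.values[:, keep],
        spot_ids=[s for s, k in zip(g.spot_ids, keep) if k],
        scaled=False,
    )


def write_usage_matrix(u, path) -> None:
    """Write a UsageMatrix as labelled TSV with missing cells encoded as ``NA``.

    0 is a legal usage value so missingness is carried by the sentinel token,
    never by zeros.
    """
    vals = u.values.astype(object).copy()
    vals[u.missing] = MISSING_TOKEN
    df = pd.DataFrame(vals, index=u.gene_ids, columns=u.spot_ids)
    with open(path, "w") as fh:
        fh.write(f"# usage_type={u.usage_type}\n")
        df.to_csv(fh, sep="\t", na_rep=MISSING_TOKEN)


def read_usage_matrix(path):
    from .apa_usage import UsageMatrix

    with open(path) as fh:
        first = fh.readline()
        usage_type = "RUD"
        if first.startswith("#"):
            for token in first[1:].strip().split():
                if token.startswith("usage_type="):
                    usage_type = token.split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(
        _io.StringIO(body), sep="\t", index_col=0,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    missing = df.isna().to_numpy()
    values = df.fillna(0.0).to_numpy(float)
    return UsageMatrix(
        gene_ids=[str(g) for g in df.index],
        spot_ids=[str(s) for s in df.columns],
        values=values,
        missing=missing,
        usage_type=usage_type,
    )
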