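"""Assign poly(A) sites to genes and genomic regions from a GFF3/GTF annotation.

Multi-transcript genes are flattened to a union model (usage is defined per
gene, not per transcript). 3' UTRs absent from the annotation are inferred as
exonic sequence downstream of the stop codon; introns are gaps between the
union exons. A configurable downstream window past the 3' UTR end recruits
intergenic sites as ``extended3UTR`` (default 1000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gffutils
import pandas as pd

from .io_formats import PolyASiteMatrix

__all__ = [
    "GeneModel",
    "AnnotationError",
    "build_gene_models",
    "assign_region",
    "annotate_sites",
]

# containment priority: lower wins
_REGION_PRIORITY = {"3UTR": 0, "intron": 2, "CDS": 3, "exon": 4}
_EXTENDED_PRIORITY = 1


class AnnotationError(ValueError):
    pass


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


@dataclass
class GeneModel:
    """Flattened union model of one gene; intervals are 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    utr3_end: Optional[int] = None

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for ivs in self.regions.values() for iv in ivs for c in iv]
        return (min(coords), max(coords)) if coords else (0, 0)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s + 1

    def region_at(self, coord: int) -> Optional[str]:
        """Highest-priority annotated region containing ``coord``, or None."""
        hits = [
            r for r, ivs in self.regions.items()
            if any(s <= coord <= e for s, e in ivs)
        ]
        if not hits:
            return None
        return min(hits, key=lambda r: _REGION_PRIORITY[r])

    def in_extended_utr(self, coord: int, extension: int) -> bool:
        if self.utr3_end is None or extension <= 0:
            return False
        if self.strand == "+":
            return self.utr3_end < coord <= self.utr3_end + extension
        return self.utr3_end - extension <= coord < self.utr3_end


def _build_one_model(gene_id: str, chrom: str, strand: str,
                     exons: list[tuple[int, int]],
                     cds: list[tuple[int, int]],
                     utr3: list[tuple[int, int]]) -> GeneModel:
    exons = _merge_intervals(exons)
    cds = _merge_intervals(cds)
    utr3 = _merge_intervals(utr3)

    if not utr3 and cds and exons:
        # exonic sequence strictly downstream of the stop codon
        if strand == "+":
            stop = max(e for _, e in cds)
            for s, e in exons:
                if e > stop:
                    utr3.append((max(s, stop + 1), e))
        else:
            stop = min(s for s, _ in cds)
            for s, e in exons:
                if s < stop:
                    utr3.append((s, min(e, stop - 1)))
        utr3 = _merge_intervals(utr3)

    introns: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))

    regions: dict[str, list[tuple[int, int]]] = {}
    if utr3:
        regions["3UTR"] = utr3
    if introns:
        regions["intron"] = introns
    if cds:
        regions["CDS"] = cds
    if exons:
        regions["exon"] = exons

    utr3_end = None
    if utr3:
        utr3_end = max(e for _, e in utr3) if strand == "+" else min(s for s, _ in utr3)

    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     regions=regions, utr3_end=utr3_end)


def build_gene_models(annotation_path) -> dict[str, GeneModel]:
    """Parse a GFF3/GTF file into one flattened :class:`GeneModel` per gene."""
    path = Path(annotation_path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_types = [t for t in db.featuretypes() if t in ("gene", "pseudogene")]
    if not gene_types:
        raise AnnotationError("annotation contains no gene features")

    models: dict[str, GeneModel] = {}
    for gtype in gene_types:
        for gene in db.features_of_type(gtype):
            gid = gene.attributes.get("gene_id", [gene.id])[0]
            exons, cds, utr3 = [], [], []
            for child in db.children(gene.id):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype.lower() in ("three_prime_utr", "3utr"):
                    utr3.append(iv)
            if not exons and not cds:
                exons = [(gene.start, gene.end)]
            if gene.strand not in ("+", "-"):
                raise AnnotationError(f"gene {gid} has no strand")
            models[gid] = _build_one_model(gid, gene.seqid, gene.strand, exons, cds, utr3)
    return models


def assign_region(site: Mapping, models: Iterable[GeneModel] | Mapping[str, GeneModel],
                  utr_extension: int = 1000) -> tuple[Optional[str], str]:
    """Assign one site record (chrom, strand, coord) to ``(gene, region)``.

    Same-strand containment wins over the downstream-extension rule; ties
    between containing genes are broken by region priority, then by the
    smaller gene. Unassignable sites return ``(None, "intergenic")``.
    """
    if isinstance(models, Mapping):
        models = models.values()
    chrom, strand, coord = site["chrom"], site["strand"], int(site["coord"])

    annotated: list[tuple[int, int, str, str]] = []
    extended: list[tuple[int, str]] = []
    for m in models:
        if m.chrom != chrom or m.strand != strand:
            continue
        region = m.region_at(coord)
        if region is not None:
            annotated.append((_REGION_PRIORITY[region], m.length, m.gene_id, region))
        elif m.in_extended_utr(coord, utr_extension):
            dist = coord - m.utr3_end if strand == "+" else m.utr3_end - coord
            extended.append((dist, m.gene_id))
    if annotated:
        _, _, gene, region = min(annotated)
        return gene, region
    if extended:
        _, gene = min(extended)
        return gene, "extended3UTR"
    return None, "intergenic"


def annotate_sites(pa: PolyASiteMatrix, models, utr_extension: int = 1000) -> PolyASiteMatrix:
    """Return a copy of ``pa`` with gene/region columns filled from the models."""
    sites = pa.sites.copy()
    genes, regions = [], []
    for _, row in sites.iterrows():
        g, r = assign_region(row, models, utr_extension)
        genes.append(g)
        regions.append(r)
    sites["gene"] = genes
    sites["region"] = regions
    return PolyASiteMatrix(
        site_ids=list(pa.site_ids), counts=pa.counts.copy(),
        sites=sites, spot_ids=list(pa.spot_ids),
    )
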