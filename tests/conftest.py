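import numpy as np
import pandas as pd
import pytest

from spotapa.apa_usage import UsageMatrix
from spotapa.io_formats import GeneSpotMatrix, PolyASiteMatrix, SpotLayout


@pytest.fixture
def tiny_pa():
    """3 genes x 4 spots; geneA/geneB have two 3' UTR sites each."""
    sites = pd.DataFrame([
        {"site_id": "a.p", "chrom": "chr1", "strand": "+", "coord": 1100,
         "gene": "geneA", "region": "3UTR"},
        {"site_id": "a.d", "chrom": "chr1", "strand": "+", "coord": 1500,
         "gene": "geneA", "region": "3UTR"},
        {"site_id": "b.p", "chrom": "chr1", "strand": "-", "coord": 2500,
         "gene": "geneB", "region": "3UTR"},
        {"site_id": "b.d", "chrom": "chr1", "strand": "-", "coord": 2100,
         "gene": "geneB", "region": "3UTR"},
        {"site_id": "c.1", "chrom": "chr2", "strand": "+", "coord": 3100,
         "gene": "geneC", "region": "3UTR"},
    ])
    counts = np.array([
        [3, 0, 4, 0],   # a.p
        [1, 0, 6, 0],   # a.d
        [2, 5, 0, 0],   # b.p
        [2, 5, 0, 3],   # b.d
        [9, 9, 9, 9],   # c.1 (single site: ineligible for RUD)
    ])
    return PolyASiteMatrix(
        site_ids=sites["site_id"].tolist(), counts=counts, sites=sites,
        spot_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def square_layout():
    """16 spots on a 4x4 grid, left half layer A, right half layer B."""
    ids = [f"s{i}" for i in range(16)]
    x = np.repeat(np.arange(4.0), 4)
    y = np.tile(np.arange(4.0), 4)
    layer = ["A" if xi < 2 else "B" for xi in x]
    return SpotLayout(spot_ids=ids, x=x, y=y, layer=layer)


def usage_from(values, missing=None, usage_type="RUD"):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    return UsageMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        spot_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values, missing=np.asarray(missing, dtype=bool),
        usage_type=usage_type,
    )


@pytest.fixture
def make_usage():
    return usage_from
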