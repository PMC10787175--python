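# spotapa

Mining spatial patterns of alternative polyadenylation (APA) from
spot-barcoded spatial transcriptomics data.

Given a poly(A)-site × spot count matrix, a gene × spot expression matrix,
and a spot layout, spotapa:

1. **annotates** poly(A) sites with genes and genomic regions from a
   GFF3/GTF annotation, recruiting intergenic sites within a configurable
   downstream window (default 1000 bp) past each gene's 3′ UTR end;
2. **quantifies** per-gene, per-spot APA usage — the relative usage of the
   distal poly(A) site (RUD) for 3′ UTR APA genes, or the highest intronic
   site ratio for intronic APA genes — with explicit missing-value
   (dropout) semantics;
3. **imputes** the sparse usage matrix with an iterative k-nearest-neighbor
   model whose spot neighborhoods come from the scaled gene-expression
   profile; the neighbor count k is chosen by a comprehensive index (sum of
   Z-scores of eight clustering-validation metrics across a k grid);
4. **detects** genes with spatial APA dynamics: differential usage between
   two layers (DEAPA), layer-specific usage (LSAPA), and spatially variable
   usage (SVAPA; built-in Moran's I permutation test, or imported results
   from external count-based detectors);
5. **summarizes** the combined gene set into spatial usage patterns by
   k-means clustering with representative-gene selection.

A first-class simulator generates layered spot layouts with planted APA
patterns and controllable dropout, so the entire pipeline is testable
offline; masking/subsampling helpers reproduce the dropout-robustness
experiment designs.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(metric brute-force oracles, imputation hand traces, seeded parameter
recovery, error calibration, k-selection behavior, toy-fixture contracts).

## CLI

All stages are subcommands of a single entry point:

```sh
spotapa simulate --n-spots 200 --seed 7 --out-prefix sim
spotapa annotate --matrix counts.mtx --sites sites.tsv --spots spots.tsv \
    --annotation genes.gff3 --out annotated_sites.tsv
spotapa usage    --matrix sim.counts.mtx --sites sim.sites.tsv \
    --spots sim.spots.tsv --mode rud --out usage.tsv
spotapa impute   --usage usage.tsv --expr sim.expr.tsv --k 10 --out imputed.tsv
spotapa select-k --usage usage.tsv --expr sim.expr.tsv --layout sim.layout.tsv \
    --kmin 2 --kmax 40 --out kscan.tsv
spotapa deapa    --usage imputed.tsv --layout sim.layout.tsv \
    --group-a L1 --group-b L2 --out deapa.tsv
spotapa lsapa    --usage imputed.tsv --layout sim.layout.tsv --out lsapa.tsv
spotapa svapa    --usage imputed.tsv --layout sim.layout.tsv --out svapa.tsv
spotapa patterns --usage imputed.tsv --genes genes.tsv \
    --layout sim.layout.tsv --out-prefix patterns
spotapa benchmark --seed 1 --out bench.tsv
```

Usage matrices are TSV with missing cells encoded as the token `NA`
(0 is a legal usage value and is never conflated with missingness).
Count matrices are Matrix Market (`.mtx`) with sidecar TSVs, or dense TSV.

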