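# coexpair

Cluster-resolved co-expression analysis of genes encoding interacting
membrane proteins in single-cell / single-nucleus UMI data.

Given a 10x-style sparse count matrix, a barcode→cluster assignment, and a
table of interacting gene pairs, the pipeline:

1. removes outlier barcodes via a central 95% interval on total UMIs and
   detected genes (`qc`);
2. normalizes counts (library-size scaling to 1e4 + log1p) and computes
   per-cluster average expression on the de-logged scale (`profiles`);
3. flags a pair as **co-expressed** in a cluster when both genes' average
   expression is ≥ a minimum threshold (default 0.15), counts retained
   pairs per cluster and in the union, and computes a per-cluster Pearson
   correlation across the retained pairs (x = first-gene average,
   y = second-gene average) (`coexpr`);
4. repeats the identical filter+correlation on randomly drawn gene pairs
   as a null control and reports Δr = r_true − mean(r_null) (`null`);
5. optionally annotates clusters from a marker table using dot-plot
   statistics (percent expressing, mean expression) and can transfer
   labels between clusterings by barcode majority vote
   (`annotate`, `transfer`).

A synthetic data generator (`coexpair.simulate`) produces clustered
negative-binomial UMI counts with planted marker genes and gene pairs whose
latent rates are correlated at a configurable level, plus a lower-depth
"nucleus" modality — so the whole pipeline is testable without any
external download.

## CLI

```sh
coexpair demo --seed 0 --out demo_out            # simulate + full pipeline
coexpair simulate --seed 1 --out fixture/        # just the synthetic bundle
coexpair qc --matrix fixture/ --out qc_out
coexpair profiles --matrix fixture/ --clusters fixture/clusters.tsv --out profile.tsv
coexpair annotate --matrix fixture/ --clusters fixture/clusters.tsv \
    --markers fixture/markers.tsv --out annot_out
coexpair coexpr --matrix fixture/ --clusters fixture/clusters.tsv \
    --pairs fixture/pairs.tsv --min-expr 0.15 --out coexpr_out
coexpair null --matrix fixture/ --clusters fixture/clusters.tsv \
    --pairs fixture/pairs.tsv --n-draws 25 --seed 0 --out null.tsv
coexpair run --config config.yaml                # full pipeline from YAML
```

`coexpair run` reads a YAML config with keys `matrix_dir`, `clusters`,
`pairs`, optional `markers`, `outdir`, `qc_level`, `coexpr:
{min_expression, pair_order, mode}`, `null: {n_draws, seed, ...}`. All
artifacts (TSV/JSON summaries and a machine-readable `run_report.json`
with versions, seeds and per-stage counts) are written to `outdir`.

Exit codes: 0 success, 2 configuration error, 3 data/format error, 4 stage
failure.

## Notes on conventions

* The 0.15 minimum-expression filter is inclusive and applied per gene;
  both genes must pass for the pair to count.
* Pearson r is undefined (reported as missing, never 0) with fewer than
  two retained pairs or zero variance on either axis.
* Per-cluster averages default to the normalized (expm1 of log1p) scale;
  `--raw-average` switches to raw UMI means.
* Within-pair order is preserved as given (it defines the correlation
  axes); `--pair-order symmetrized` canonicalizes pairs lexicographically.
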