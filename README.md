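# crossclust

Cross-species single-cell cluster homology. Given two clustered
single-cell count matrices (a "source" and a "target" species) and an
ortholog table, `crossclust`:

1. log-normalizes counts (library size, scale factor 10,000);
2. finds per-cluster marker genes with a tie-corrected Wilcoxon
   rank-sum test (one-vs-rest) and an average log fold change;
3. builds one gene set per source cluster from its top mapped positive
   markers (default: walk the significance-sorted markers, keep genes
   with at least one ortholog, stop after 100 mapped genes);
4. builds one ranked gene list per target cluster scored by
   signedP = sign(logFC) × −log10(p) (or by avg_logFC);
5. scores every (set, list) pair with a from-scratch preranked
   enrichment: weighted KS running sum, gene-permutation null,
   NES, add-one p-values, BH correction, size window [15, 500];
6. assembles the source × target homology matrix, calls the best
   source match per target cluster (max positive NES with padj ≤ α),
   and renders a diverging heatmap.

A negative-binomial simulator generates paired datasets with planted
ortholog-linked cluster correspondences and ground truth, so the whole
pipeline is testable without any download.

## CLI

```sh
# make a synthetic paired dataset (counts as MatrixMarket + TSV sidecars,
# labels, ortholog table, truth.json)
crossclust simulate --outdir data/ --seed 1 \
    --source-clusters 6 --target-clusters 8 --n-matched 5
# --paper-shape gives the published 10x18 / 6146+12073-cell geometry

# all-in-one run (six report files in out/)
crossclust run --dataset-dir data/ --outdir out/ --seed 1 --n-perm 10000

# or stage by stage
crossclust markers  --counts data/source_counts.mtx --genes data/source_genes.tsv \
    --cells data/source_cells.tsv --labels data/source_labels.tsv --out src_markers.tsv
crossclust markers  --mode full --counts data/target_counts.mtx ... --out tgt_markers.tsv
crossclust crossmap --source-markers src_markers.tsv --target-markers tgt_markers.tsv \
    --orthologs data/orthologs.tsv --gmt sets.gmt --rnk-dir rnk/
crossclust gsea     --gmt sets.gmt --rnk-dir rnk/ --out matrix.json --seed 1
crossclust report   --matrix matrix.json --outdir out/
```

`crossclust run` writes: `enrichment_results.tsv`,
`homology_matrix.tsv` (NES grid, `NA` = rejected pair),
`homology_matrix.json`, `match_calls.tsv`, `heatmap.png`,
`run_metadata.json`. A YAML config (`--config`) can set every knob;
unknown keys are rejected. Exit codes: 0 ok, 2 input error, 3 stage
failure.

Key knobs (defaults): `--scale-factor 1e4`, `--top-n 100`,
`--metric signedP`, `--n-perm 10000`, `--min-size 15`, `--max-size 500`,
`--weight 1.0`, `--alpha 0.05`, marker thresholds `min_pct 0.1` /
`logfc_threshold 0.25` (natural-log fold change, pseudocount 1).

Notes on statistics: p-values come from a plain gene-permutation null
with the add-one estimator (floored at 1/(n_perm+1)), not an adaptive
multilevel scheme; per-pair RNG streams are derived from
(seed, target id, source id), so results are independent of evaluation
order. BH is applied within each target cluster across source sets by
default (`--bh-scope global` for a matrix-wide adjustment).

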