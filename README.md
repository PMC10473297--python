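# cofluct

Peak co-fluctuation analysis for parcellated time series: exact edge
time-series decomposition of functional connectivity, RMS peak/segment
extraction, Lin's-concordance similarity, a recursive significance-gated
hierarchical modularity-maximization clustering, and the downstream
characterization analyses (centroids, bipartition templates,
data-requirement curves) — all exercised end to end on synthetic
multi-scan data with planted co-fluctuation states.

## What it does

1. **I/O & censoring** (`cofluct.io_masks`) — read frames x parcels
   matrices (TSV/CSV/HDF5) with binary censor masks; frames within 2 TRs
   of a censored frame are removed and surviving stretches shorter than
   5 TRs discarded.
2. **Edge dynamics** (`cofluct.edges`) — z-score parcels over retained
   frames, form framewise edge products `z_i(t) z_j(t)` (their temporal
   mean is exactly the Pearson FC), compute the global RMS amplitude
   R(t), segment it trough to trough, and keep peaks passing prominence
   (> 0.25) and 10-s separation filters; amplitude classes
   (high / n.s. / low) come from circular-shift surrogate percentiles.
3. **Concordance** (`cofluct.concordance`) — Lin's concordance
   `2 Cov / (Var_x + Var_y + (mu_x - mu_y)^2)`, which penalizes amplitude
   mismatch and is bounded by |Pearson r|.
4. **Hierarchical clustering** (`cofluct.hierarchy`) — modularity matrix
   `B = C - mean(upper triangle)`, a bespoke signed-modularity Louvain
   (with Kernighan-Lin refinement), permutation-null consensus over an
   ensemble of runs, per-community permutation tests of the local
   modularity q_c, and recursion into communities passing p < 0.05,
   size >= 5, and >= 2 distinct scans.
5. **Characterization** (`cofluct.characterize`) — centroids, leading
   eigenmodes (PC1 + variance explained), system averages, FC
   correlations, hierarchical depth curves, amplitude composition.
6. **Bipartitions** (`cofluct.bipartitions`) — sign bipartitions of
   frames, co-assignment matrices, exhaustive system-template enumeration
   (2^(S-1) - 1 templates; 8,191 for S = 14), NMI matching, weighted
   templates.
7. **Data requirement** (`cofluct.datareq`) — split-half scan-incremental
   centroid-convergence curves, reindexable from scans to samples.
8. **Synthetic data** (`cofluct.synthetic`) — multi-scan generators with
   planted (optionally two-level) recurring rank-1 co-fluctuation states,
   burst censoring, and circular-shift surrogates.

## CLI

All stages are exposed under a single entry point:

```sh
cofluct simulate  --config cfg.yaml --out sim/            # scans + manifest
cofluct peaks     --manifest sim/manifest.json --out peaks/
cofluct cluster   --patterns peaks/ --seed 1 --out clus/
cofluct characterize --patterns peaks/ --hierarchy clus/hierarchy.json
cofluct templates --manifest sim/manifest.json --patterns peaks/
cofluct datareq   --patterns peaks/ --labels clus/labels.tsv
cofluct run-all   --config cfg.yaml --seed 1 --out all/   # end to end
```

`cfg.yaml` is the YAML serialization of `cofluct.config.RunConfig`
(defaults: pad 2 frames, min run 5, prominence 0.25, separation 10 s,
1000 Louvain runs, 10,000 permutations, alpha 0.05, min size 5, min
scans 2). A single master seed fans out deterministically to every
stage; every output directory carries a provenance record with the
config hash and the peak-count funnel.

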