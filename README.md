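# minetkit

Metabolic interaction networks from genome-scale metabolic models
(GSMMs): a self-contained library and CLI covering the full chain

1. **Model I/O** — read/write the SBML Level 3 + FBC v2 subset emitted by
   automated reconstruction tools (bounds default to ±1000 mmol/gDW/h),
   plus deterministic toy/random model generators so nothing needs to be
   downloaded.
2. **Seed sets** — build each model's directed substrate→product
   metabolite graph, find strongly connected components, and detect seed
   metabolites (source SCCs of size ≤ `MaxCC`, default 5) with
   confidences C = 1/|SCC|.
3. **Pairwise indices** — asymmetric competition (confidence-weighted
   seed overlap) and complementarity (fraction of A's seeds producible by
   B) indices in [0,1]; potentially transferable metabolites (PTMs,
   seeds(A) ∩ nonseeds(B)); record tables and max-symmetrized matrices.
4. **Flux distances** — FBA then parsimonious FBA (minimize Σ|v| at fixed
   optimum, deterministic HiGHS LPs), flux vectors over reactions active
   in ≥1 model, raw and per-reaction-standardized Euclidean distances.
5. **Thresholds** — RMT scan (eigenvalue unfolding, nearest-neighbour
   spacings tested against Poisson with chi-square or Kolmogorov–Smirnov),
   standard/modified Z-score outlier detection (0.6745·MAD), and final
   adjacency construction.
6. **Network analysis** — global properties, degree/betweenness/stress/
   clustering centralities, greedy-modularity modules, z_i–P_i hub roles
   (thresholds 2.5 / 0.62), attribute merging, network intersection.
7. **Exports** — directed bipartite microbe–metabolite PTM network and
   clustered heatmap data for distance matrices.

## CLI

Every stage is a subcommand of `minetkit` (also runnable as
`python -m minetkit.cli`). A complete run on the bundled 7-model demo
set:

```sh
minetkit simulate-models --out demo_models
minetkit pipeline --models demo_models --out results_demo \
    --threshold-method value --threshold-value 0.5
```

which writes seed sets, the n² pairwise index table, PTMs, both index
matrices, raw/standardized distance matrices with the long pair table,
the thresholded adjacency, global/node/module/z_i–P_i tables, the PTM
bipartite network, heatmap data, and a `provenance.json` record.
Re-running with the same inputs reproduces every file byte-for-byte.

Individual stages: `seedset`, `phylomint`, `ptm`, `matrix`, `distance`,
`threshold-rmt`, `threshold-zscore`, `build-network`, `net-props`,
`modules`, `merge-attrs`, `intersect`, `ptm-network`, `heatmap`. Models
are accepted as a directory of SBML files or a flat zip archive. See
`minetkit <command> --help` for options.

Notes:
- The RMT scan requires a symmetric matrix with values in [0,1] and at
  least 10 nodes surviving the cutoff; convert distance matrices with
  the affine inversion (`distance_to_similarity`) first.
- The Z-score route works directly on distance or index values; the
  modified (median/MAD) method is the default, cutoff 2.698 (3.5 is the
  common alternative).

## Layout

```
src/minetkit/
  gsmm_io.py      SBML-FBC I/O, archives, toy/random/demo model generators
  seedset.py      metabolite graph, SCCs, seed detection + brute-force oracle
  phylomint.py    competition/complementarity indices, PTMs, matrices
  flux.py         FBA, pFBA, flux tables, Euclidean/standardized distances
  threshold.py    RMT scan, spacing tests, Z-scores, adjacency construction
  netanalysis.py  global properties, centralities, modules, z_i–P_i, merge
  export.py       PTM bipartite network, heatmap ordering/rendering
  matrix.py       labeled square matrix container (TSV round-trip)
  cli.py          click CLI, one subcommand per stage + `pipeline`
```
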