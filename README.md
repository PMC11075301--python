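# menkit

Molecular ecological network (MEN) analysis for longitudinal microbiome
count tables: from ASV count matrices through correlation-thresholded
co-occurrence networks to the standard per-network index panel,
stability simulations and time-series analyses.

## What it does

- **Synthetic communities** (`menkit.synthetic`) — compositional
  log-normal count tables for two groups across monthly time points,
  with planted correlation blocks and a decaying treatment effect
  (reduced richness, boosted dominant taxa, weakened block
  correlation), plus planted-clique pathway tables. Ground truth is
  retained for recovery tests.
- **Table preprocessing** (`menkit.table_io`) — TSV feature-table I/O
  with validation, per-time-point low-abundance filtering, rarefaction
  without replacement, half-prevalence filtering and log transform.
- **Diversity** (`menkit.diversity`) — Chao1 / Shannon / Simpson
  dominance, Bray–Curtis distances, classical PCoA, and permutation
  tests (ANOSIM, one-factor PERMANOVA, MRPP) with seeded permutation
  p-values, plus a Shapiro-gated t-test / Wilcoxon two-group rule.
- **RMT thresholding** (`menkit.rmt`) — Pearson correlation matrices,
  eigenvalue unfolding, nearest-neighbour spacing statistics, and a
  threshold scan that picks the cutoff where the spectrum transitions
  from GOE to Poisson statistics; signed network construction.
- **Topology** (`menkit.topology`) — node/link counts, average degree
  and clustering, geodesic distance over reachable pairs,
  connectedness, P/N ratio, log–log scale-free fit, and
  Maslov–Sneppen degree-preserving null ensembles with z-scores.
- **Modules and roles** (`menkit.modules`) — greedy modularity
  communities, relative modularity against the null ensemble,
  small/large module summaries, and Zi–Pi role classification
  (peripherals, connectors, module hubs, network hubs; the latter
  three are keystones).
- **Stability** (`menkit.stability`) — global efficiency,
  vulnerability (worst single-node efficiency drop), and robustness
  under random 50% or targeted module-hub removal with pruning of
  isolated survivors.
- **Trends** (`menkit.trends`) — per-parameter regression against
  time, logFC(A/C) series, and Spearman/Pearson correlation matrices
  linking network complexity and stability.
- **Functional networks** (`menkit.funcnet`) — pathway Pearson
  networks and MCODE-style core-cluster extraction (vertex weights
  from the highest k-core of each neighbourhood, greedy seeded
  expansion, haircut, k-core filter), plus cluster-overlap counts.

## CLI

```bash
menkit all -o results --seed 1                 # full synthetic run
menkit simulate -c config.yaml -o results      # single stages:
menkit filter ... ; menkit diversity ... ; menkit network ...
menkit stability ... ; menkit trends ... ; menkit funcnet ...
```

Configuration is YAML merged over built-in defaults (see
`menkit.pipeline.DEFAULT_CONFIG`); `--seed` and `--output-dir`
override the file. Real data are supplied via

```yaml
simulate: {enabled: false}
input:
  table: my_counts.tsv      # rows = ASVs, first column "#OTU ID"
  metadata: my_metadata.tsv # sample_id, group, month, subject
```

Every run writes TSV outputs (index panel with one row per
group × month, node roles, stability, regressions,
complexity–stability correlations, MCODE clusters), GraphML networks
and a manifest with the config hash and seed; identical config + seed
gives byte-identical results. Exit codes: 0 ok, 1 stage failure,
2 configuration error.

The network stage defaults to a fixed correlation cutoff
(`network.fixed_threshold`), which is appropriate for small per-network
sample counts; set `network.threshold_method: rmt` to select the cutoff
from the eigenvalue spacing transition instead (needs enough ASVs for
at least `min_eigs` distinct eigenvalues).

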