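# Methods

## Model and assumptions

`netexpand` treats trait genetics as a diffusion problem on a protein
interaction network. The working assumptions are:

- **Guilt by association.** Genes causally involved in a trait lie close to
  each other in the interactome, so a random walk restarted at GWAS seed
  genes concentrates probability mass on other trait-relevant genes.
- **Seed confidence is informative.** Seeds carry locus-to-gene (L2G)
  scores in [0.5, 1]; these weight the restart vector, so better-supported
  seeds contribute more diffusion mass.
- **Modules are communities.** Trait-relevant biology is organized into
  densely interacting gene groups, recoverable by random-walk community
  detection among the genes with the highest propagation scores.
- **Pleiotropy is module reuse.** Two traits share biology when their
  detected modules overlap almost completely (Jaccard ≥ 0.70), not merely
  when they share a few genes.

The propagation solves `s = (1 − α)·p + α·W·s`, where `W = A·D⁻¹` is the
column-normalized adjacency, `p` the seed weights normalized to sum 1, and
`α` the damping (continuation) probability. Probability leaving
degree-zero nodes is redistributed according to `p`, so `Σ s = 1` exactly;
the solver is sparse power iteration, stopped when the L1 change falls
below `1e-12`, and batches many restart vectors as matrix columns (the
leave-one-out and null ensembles are hundreds of propagations).

## Key parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `damping` α | 0.85 | continuation probability of the walk; the universal PageRank default that standard graph libraries apply |
| Q3 cut | top 25 % | genes with score strictly above the third quartile (type-7 linear-interpolation quantile) enter clustering |
| `walktrap_steps` | 8 | random-walk length for community distances; longer than the generic library default (4) because short walks spuriously split single dense communities at the network sizes this package ships with (see limitations) |
| `max_module_size` | 300 genes | communities above this are re-clustered recursively; a guard accepts a community that refuses to split after 3 attempts (e.g. a large clique) |
| `min_genes`, `min_seeds` | 10, 2 | only communities with ≥ 10 genes and ≥ 2 seeds are tested for trait association |
| `alpha` | 0.05 | BH-adjusted significance threshold, applied per trait across its eligible modules |
| `jaccard_threshold` | 0.70 | minimum gene overlap for two modules to be the "same" module across traits; collapsing takes connected components of this relation |
| `linkage`, heights | complete, 1.0 / 0.7 | hierarchical clustering of traits on Manhattan distances between rank-score vectors; distances are max-normalized to [0, 1] by default so the height cut-offs are scale-free |
| `n_perm`, `n_null` | 1000 | permutation-null sizes for benchmark Z-scores and percentile ensembles |
| `merge_window_bp` | 200 000 | loci with lead variants within this distance are merged (single linkage); per-gene L2G is averaged across merged loci |
| `snp_window_bp` | 10 000 | a gene's GWAS signal is the minimum SNP p-value within this distance of its footprint |
| percentile filters | 90 / 80 / 0.1 | a candidate needs percentile > 90 and L2G > 0.1, with no other locus gene above percentile 80 and L2G 0.1 |
| percentile bins | 50–70, 70–80, 80–90, 90–95, 95–100 | bins for the SNP-p enrichment, each tested against the percentile < 50 reference |

All of these live in `PipelineConfig` (YAML-overridable); every random
draw in the pipeline derives from its single `rng_seed`.

## Statistical choices

- **Module test.** One-sided two-sample KS on the genome-wide PPR ranks of
  module genes versus the other clustered genes. The module is *excluded*
  from the background sample by default: at small network sizes a module
  can span most of the clustered genes, and retaining it bounds the KS
  statistic by the complement fraction, leaving the test without power
  regardless of signal. Retention is available
  (`include_module_in_background=True`) and is inconsequential whenever
  modules are small relative to the background.
- **AUC.** Mann–Whitney form with half-credit for ties, over the evaluable
  universe (network genes minus the trait's own seeds — positives that are
  seeds are removed first to avoid circularity). Z-scores use the sample
  (n−1) standard deviation of the null AUCs.
- **Degree-preserving null.** Node labels are permuted within exact-degree
  classes, preserving topology and every degree exactly; double-edge-swap
  rewiring (10·|E| swaps) is available as the alternative null.
- **Percentiles.** A gene's percentile is the fraction of null runs with a
  strictly lower score for that gene, plus half the ties, × 100. Null seed
  sets match the size of the leave-one-out input (N − 1 genes) and are
  drawn uniformly from network nodes.
- **Odds ratios.** Zero-cell odds ratios are reported as 0 / `inf`
  sentinels; the accompanying confidence interval is a Woolf (log) interval
  with a 0.5 continuity correction. Bins with no genes are dropped.
- **Ties and determinism.** Score ties in the rank transform break
  lexicographically by gene identifier; node order entering every numeric
  routine is sorted; identical config + seed reproduce all output files
  byte for byte.

## What the synthetic scenario emulates — and what it does not

The generator produces a planted-partition graph (default 5 blocks × 60
genes, within-block edge probability 0.2, between-block 0.01), traits whose
seeds concentrate in one causal block (8 seeds, 20 % drawn uniformly
elsewhere, L2G ~ U(0.5, 1)), gold standards made of causal-block genes
never used as seeds, and GWAS summaries in which SNPs within 10 kb of
causal-block gene footprints draw p-values from Beta(0.05, 1) (null genes
U(0, 1)) on a linear genome of 20 kb footprints separated by 30 kb gaps,
with gene order decorrelated from block membership so loci mix causal and
decoy genes. For the locus-prioritization scenario the seed list is taken
noise-free, mirroring a curated high-confidence gene list, and the
"low p-value" threshold is set to 1e-3, at which planted signal is near
certain per causal gene and null genes qualify rarely.

This captures the statistical structure the method relies on — modular
topology, seed concentration, seed-disjoint gold standards, genomic
clustering of association signal — but not: realistic degree distributions
(hubs), linkage disequilibrium, overlapping or nested pathway membership,
tissue specificity, or annotation noise in real L2G scores. Passing tests
on this scenario demonstrate that the machinery is correct and calibrated,
not that real-data performance will match.

Test and acceptance runs use this desk scale throughout (300–400-gene
networks, 20 traits, 200–1000-draw null ensembles, 20 replicates per
stochastic claim), chosen so a full end-to-end run completes in seconds
while every statistical check retains power.

## Known limitations

- **Community detection at small scale.** On the desk-scale scenario the
  top-quartile subgraph is typically one dense block plus loosely attached
  neighbours. Maximum-modularity cuts of the walktrap dendrogram split
  such a single dense community spuriously in roughly a fifth of
  replicates (modularity optima on dense near-random graphs are known to
  be non-trivial), in which case the causal block is recovered as two
  halves rather than one module. Longer walks (the steps default of 8)
  mitigate but do not eliminate this; on networks of realistic size, where
  any one module is a small fraction of the clustered genes, the effect is
  not expected. Planted-block recovery measured over many replicates is
  ~0.8 at these sizes.
- **KS power with dominant modules.** Even with the module-excluded
  background, a module covering nearly all clustered genes is tested
  against a small complement and may not reach significance despite
  perfect recovery.
- **No edge directionality.** Signalling direction is ignored; the walk is
  on the undirected simple graph.
- **Percentile granularity.** With `n_null` runs the percentile resolution
  is 100/n_null; Monte-Carlo noise shrinks as 1/√n_null.
- **The L2G model itself is an input.** Seed selection quality bounds what
  propagation can recover; the package consumes, never re-estimates, those
  scores.
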