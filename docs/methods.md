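# Methods

This note documents the models and procedures implemented in `scskin`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish about real data.

## Synthetic atlas generator

`simulate.simulate_atlas` draws UMI counts from a gamma-Poisson (negative
binomial) model: gene *g* in cell *i* has mean `base_mean_g · s(g, i)` and
variance `μ + φ μ²` with dispersion `φ = nb_dispersion` (default 0.5, a
typical droplet-data value; `φ = 0` degenerates to Poisson).

- **Baseline heterogeneity.** Per-gene baseline means are lognormal around
  `base_mean` (log-sd `base_mean_sigma = 1.0`). This matters: with a single
  shared baseline, background sampling noise at low means has the same
  coefficient of variation as a genuinely bimodal marker, and no
  mean-trend method could separate them. Planted marker and
  condition-response genes draw from the upper tail (≥ `base_mean`), since
  real marker genes are well expressed.
- **Planted structure.** Each of K types owns a disjoint block of
  `marker_genes_per_type` markers scaled by `2^marker_log2fc` in that type,
  and `de_genes_per_type` condition-response genes scaled by
  `±2^de_log2fc` in disease-condition cells of that type (first half up,
  second half down; planted sender ligands occupy the up half and are named
  `LIG<type>_<j>`). Cell counts per (type, condition, donor) are Poisson
  around the configured expectations — lists per type plant composition
  shifts. Defaults give 8 types × ~100 cells over 3 + 3 donors.
- **Artifacts.** Doublets are sums of two singlet profiles from distinct
  types at rate `doublet_rate`. High-mitochondria cells (a configurable
  fraction) have their `MT-`-prefixed gene counts inflated to a target
  mito share (default 0.25, well above the 5% QC threshold).
- **Negative control.** `randomize_matrix` permutes each gene's counts
  independently across cells: cell identity is destroyed while each gene's
  value multiset (mean, variance, detection rate) is preserved exactly.
  Permuting genes-within-cells instead would also destroy per-gene
  statistics; the per-gene variant is the strictest control that keeps
  them, and the granularity is overridable in principle by permuting the
  transpose.
- **Second species.** `rename_species` re-cases symbols (KRT14 → Krt14),
  emulating 1:1 same-name orthologs; all cross-matching in the package is
  case-insensitive, so projection through a trained model is exactly
  invariant. Genuinely renamed orthologs require a user ortholog table.

What the generator does **not** model: batch/donor effects, ambient RNA,
UMI saturation, gene-gene correlation beyond the planted blocks, and
continuous (trajectory-like) identity. Passing tests therefore demonstrate
correctness of the machinery and adequate power under clean separation,
not performance on confounded real data.

## Quality control

Per cell: detected genes (nonzero count), total UMIs, and mitochondrial UMI
share (genes under a configurable prefix, default `MT-`). Filtering removes
strict violators of `min_genes = 500`, `min_umi = 1000`,
`max_mito_frac = 0.05` — boundary values survive — plus predicted doublets.
The shipped thresholds suit deeply sequenced real data; the compact
synthetic atlas is shallower, so examples scale them down explicitly.

Doublet prediction is the standard simulated-doublet scheme: synthetic
doublets (2× the observed cells) are formed by summing random cell pairs;
all cells are embedded by PCA (30 PCs) of log-normalized expression; each
observed cell's score is a likelihood-corrected fraction of synthetic
doublets among its 20 nearest neighbors (correcting for the simulated pool
size and the prior doublet rate, so singlets score near the prior and true
doublets near 1). The flagged set is the stricter of the top
`expected_rate` fraction and an Otsu threshold on the score histogram; with
`expected_rate = 0` nothing is flagged. The expected rate is an input, as
in droplet protocols where it follows from loading density.

## Normalization

Counts-per-10k (CP10k) depth normalization; `log1p(CP10k)` is the scale for
PCA, classifier features and rank tests. Detection fractions always use raw
counts. The enrichment score's mean ratio deliberately uses **linear**
CP10k means (see below).

## Overdispersed genes and clustering

Candidate features are genes with the largest positive residual of log CV
over a mean-trend baseline: genes are binned into 20 mean-quantile bins
(≥ 5 genes per bin) and the baseline is the bin's 25th percentile of
log CV. A lower quantile rather than the median is used because genuinely
variable genes can be locally abundant in a mean range (in planted
simulations they dominate whole bins); the lower quantile stays anchored to
the non-variable bulk. Cell-cycle genes, if supplied, are removed first.

Clustering: log-normalize, PCA to `n_pcs = 20`, symmetrized kNN graph
(`n_neighbors = 15`), Louvain community detection at `resolution = 1.0`
(defaults at the midpoints of the conventional working ranges 5–25 /
0.8–1.5), seeded and with communities relabeled by size then first member
for determinism. Sub-clustering re-runs the full recipe (fresh
overdispersed genes) on one main cluster's cells, namespacing labels
`main.sub`; `merge_or_split` applies explicit relabeling maps.

## Marker enrichment score and permutation FPR

`E(g, c) = ((f_in + ε)/(f_out + ε)) · ((μ_in + ε)/(μ_out + ε))`, `ε = 0.01`
(configurable). μ is the linear CP10k mean: with log-compressed means, a
strong marker whose detection saturates both in and out of its type scores
barely above 1 and is outranked by detection noise of rare genes, whereas
linear means keep a k-fold marker at a k-fold μ-ratio regardless of
absolute expression. The reported `log2_fold_change` is
`log2((μ_in + ε)/(μ_out + ε))`.

The FPR is a label permutation test preserving cluster sizes
(`n_perm = 1000` by default; tests and the pipeline use 100–200, adequate
for a 0.1 cutoff). It is add-one corrected, so the minimum attainable fpr
is `1/(n_perm + 1)` and an observed score that never wins reports exactly
1.0. Significance: fpr < 0.1. Calibration: under globally shuffled labels
≤ 15% of (gene, cluster) pairs pass, consistent with the cutoff.

## Identity classifier

Panel: per cluster, significant markers sorted by fold change (ties by gene
name), top `k = 30`, deduplicated keeping the first contributing cluster.
Features: `log1p(CP10k)` restricted to the panel, standardized per gene
with training-set statistics; query matrices are matched by case-normalized
symbol, missing panel genes zero-imputed (error above 50% missing).

Network: one hidden layer of 64 ReLU units, softmax output, cross-entropy,
Adam (lr 1e-3, batch 32, 100 epochs), seeded initialization and shuffling —
fully deterministic. Two regularizers are on by default: label smoothing
0.1 and weight decay 1e-3. They leave accuracy on separated data unchanged
but calibrate confidence off-manifold: without them ~6% of
per-gene-randomized cells were still assigned to their original type with
posterior ≥ 0.5; with them the control fraction is ~0. "Significantly
assigned" in the negative control means posterior ≥ 0.5 for the original
cluster (threshold configurable and reported).

Validation: stratified k-fold cross-validation (overall accuracy and
per-class recall); on the default synthetic atlas 5-fold accuracy is 1.0,
comfortably above the 80% working bar for real atlases. Radar coordinates
place the K classes at angles 2πi/K on the unit circle and each cell at its
posterior-weighted anchor average: one-hot cells land on anchors, uniform
cells at the origin.

## Condition contrasts

- **Composition:** per cluster, 2×2 Fisher exact test (in-cluster vs rest ×
  control vs disease) over pooled cells, BH across clusters, significant at
  FDR < 0.01. Pooling across donors is the default; a donor-aware variant
  would require a mixed model and is out of scope.
- **Differential expression:** per cluster, genes detected in ≥ 10% of the
  cluster's cells, two-sided Wilcoxon rank-sum (Mann–Whitney) on
  log-normalized expression, BH within cluster; `log2fc` from linear
  normalized condition means with ε = 0.01. Clusters with < 3 cells in
  either condition are skipped with a warning. Null simulations give
  ~uniform p-values (fraction < 0.05 within [0.02, 0.08]).
- **Susceptibility loci:** a locus target gene has *significant existence*
  in a cluster if it is a significant marker there, or expressed (≥ 10%
  detection) with enrichment score > 1 at fpr < 0.1. Loci significant
  nowhere (or absent from the matrix) are reported unassigned rather than
  erroring.

## GO enrichment

The ontology arrives as two TSVs (child→parent edges with namespace;
gene→term annotations); only the biological_process namespace is kept by
default. Annotations are propagated upward (idempotent; cycles are a hard
error naming one cycle). Per term with ≥ 3 annotated background genes, the
hypergeometric upper tail `P(X ≥ k)` is computed exactly (verified against
brute-force rational enumeration in tests); BH across tested terms,
significant at FDR < 0.05 (the threshold is a package default, configurable).
For plotting, the subgraph of significant terms plus their root paths is
extracted, flagging *terminal* terms — significant with no significant
descendant, i.e. the most specific enriched processes.

## Ligand-receptor ratio

Per sender, candidate ligands are disease-upregulated genes ∩ catalogue
ligands. Per receiver, eligible receptors are catalogue receptors detected
in ≥ 10% of the receiver's disease cells and not significantly
downregulated ("constant or upregulated"). For each ordered type pair,
total events are catalogue pairs with ligand detected (≥ 10%) in the sender
and receptor eligible in the receiver; active events additionally require
the ligand upregulated. The denominator is restricted to expressible pairs
so the ratio reads as "fraction of possible events that are
condition-activated"; counting all catalogue pairs instead
(`denominator="all"`) is exposed because the choice is genuinely open —
the expressed denominator is the default as the more interpretable one.
Autocrine pairs are allowed and flagged. Top selection: fixed cutoff 0.35,
or the knee of the descending ratio curve (maximum perpendicular distance
to the first-last chord), falling back to the fixed cutoff for < 3 or flat
curves. Chord and Sankey export tables are lexicographically ordered for
reproducibility.

## Pipeline and problem sizes

`pipeline.run_all` executes qc → cluster → markers → classifier →
contrasts → go → lr from one YAML-able config with a single seed, writes
one TSV per stage plus a manifest (version, seed, parameters, per-stage
counts, no timestamps), and is byte-reproducible under a fixed config.
Validation (all input paths exist) happens before any compute; `--dry-run`
stops there.

Tests and examples run on compact atlases (≈ 400–2000 cells, 600–2000
genes, 100–200 permutations) — sizes chosen so the planted effects are
detected with comfortable margins while the whole suite stays fast; all
scale linearly if increased.

## Known limitations

- Pooled (donor-agnostic) composition and DE tests treat cells as
  independent; with few donors this overstates confidence on real data.
- The doublet predictor assumes discrete, separated types; embedded or
  continuous populations lower its recall.
- The enrichment score's ε couples to the CP10k scale; extremely shallow
  cells inflate normalized means.
- Cross-species projection without an ortholog table relies on 1:1
  same-name symbols; paralog families need an explicit mapping.
- The L-R score counts events, not magnitudes: a pair barely over the
  detection thresholds counts as much as a dominant axis.
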