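# scskin

Single-cell transcriptomic analysis of two-condition skin atlases: quality
control, two-level Louvain clustering, marker-gene enrichment scoring with a
permutation false positive rate, neural-network probabilistic cell-identity
scoring (with cross-species projection and a randomized negative control),
condition contrasts (cell-type composition, per-type differential
expression, susceptibility-locus mapping), GO-bioprocess enrichment, and a
modified ligand-receptor interaction score.

The package is aimed at analysts comparing diseased and healthy tissue at
single-cell resolution — the motivating setting is psoriatic vs healthy
full-thickness human skin — who want each analytical step available as a
plain, tested Python function. A synthetic atlas generator with planted
ground truth (markers, condition-response genes, composition shifts,
doublets, high-mitochondria cells, ligand axes, a renamed-ortholog
"species") makes every stage testable offline.

## The statistics at the core

**Marker enrichment score.** For gene *g* and cluster *c*, with detection
fraction *f* (share of cells with a nonzero count) and mean depth-normalized
expression *μ* inside/outside the cluster,

    E(g, c) = ((f_in + ε) / (f_out + ε)) · ((μ_in + ε) / (μ_out + ε)),   ε = 0.01

Significance is a permutation false positive rate: cluster labels are
shuffled (sizes preserved), E recomputed, and fpr(g, c) is the fraction of
null scores ≥ the observed one; markers pass at **fpr < 0.1**.

**Probabilistic cell identity.** Top-k significant markers per cluster
(ranked by fold change) form the feature panel; a single-hidden-layer
softmax network (64 ReLU units, cross-entropy with label smoothing, Adam)
maps each cell to a posterior over cell types. Validation is stratified
k-fold cross-validation plus a negative control in which every gene's
counts are permuted across cells — an informative model should then assign
(essentially) no cell confidently to its original type.

**Ligand-receptor ratio.** For an ordered (sender, receiver) type pair, the
score is

    ratio = active events / total events

where total events are catalogue pairs whose ligand is detected in the
sender and whose receptor is "constant or upregulated" in the receiver
(detected in ≥ 10% of disease cells, not significantly downregulated), and
active events are the subset whose ligand is disease-upregulated in the
sender. Top interactions are kept at ratio ≥ 0.35 (or a knee-point cutoff).

Composition shifts use per-cluster Fisher exact tests (FDR < 0.01), DE uses
per-cluster Wilcoxon rank-sum tests with Benjamini–Hochberg correction, and
GO enrichment is hypergeometric over an upward-propagated annotation DAG.

## Worked example

`examples/` holds one short script per capability. Training and validating
the identity classifier on the default synthetic atlas
(`python examples/03_identity_classifier.py`) prints:

```
feature panel: 240 genes from 8 cell types
5-fold cross-validation accuracy: 100.0%
randomized negative control: 0.00% of scrambled cells still confidently assigned to their own type (expect ~0)
cross-species projection identical to direct scoring: True
radar coordinates span [-0.91, 0.92] x [-0.91, 0.91]
```

Reading: the panel pools the top fold-change-ranked significant markers of
the 8 planted cell types; held-out cells are classified essentially
perfectly on this well-separated atlas; after per-gene randomization no
cell keeps a confident correct assignment, confirming the model reads cell
identity rather than per-gene statistics; re-cased mouse-style gene symbols
project through the model unchanged; and cells sit near their type's anchor
in radar coordinates (confident assignments approach the unit circle).

`examples/06_full_pipeline.py` runs all seven stages (qc → cluster →
markers → classifier → contrasts → go → lr) from files via one config and
prints the run manifest; re-running the same config reproduces
byte-identical outputs. A thin CLI mirrors the common entry points:
`scskin simulate`, `scskin qc`, `scskin cluster`, `scskin run-all`.

## Layout

- `src/scskin/` — library modules: `io`, `simulate`, `qc`, `cluster`,
  `markers`, `classifier`, `contrasts`, `go`, `lr`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite (unit, property and end-to-end checks)
- `docs/methods.md` — models, assumptions, parameter choices, limitations
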