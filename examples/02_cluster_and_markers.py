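"""Cluster the atlas and score marker genes with the permutation-FPR
enrichment score.

Overdispersed genes feed PCA + kNN + Louvain; each (gene, cluster) pair gets
an enrichment score E (detection-ratio x mean-expression-ratio) and a
label-permutation false positive rate; markers are significant at fpr < 0.1.
"""

from sklearn.metrics import adjusted_rand_score

from scskin.cluster import ClusterParams, cluster_cells, select_overdispersed
from scskin.markers import enrichment_scores, marker_fpr, significant_markers
from scskin.simulate import SimConfig, simulate_atlas

cm, meta, truth = simulate_atlas(SimConfig(seed=1))

overdispersed = select_overdispersed(cm, n_top=500)
labels = cluster_cells(cm.subset_genes(overdispersed), ClusterParams(seed=1))
ari = adjusted_rand_score(truth.true_type, labels)
print(f"{len(set(labels.tolist()))} Louvain clusters, "
      f"ARI vs planted types: {ari:.3f}")

markers = marker_fpr(cm, labels, enrichment_scores(cm, labels),
                     n_perm=200, seed=1)
sig = significant_markers(markers)
print(f"{len(sig)} significant (gene, cluster) marker rows at fpr < 0.1")

top = (sig.sort_values("enrichment_score", ascending=False)
       .groupby("cluster").head(3)
       .sort_values(["cluster", "enrichment_score"], ascending=[True, False]))
print(top[["cluster", "gene", "enrichment_score", "log2_fold_change", "fpr"]]
      .head(9).to_string(index=False))
# High E with low fpr marks genes detected and expressed far above the rest
# of the atlas - the candidates used to build classifier panels.
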