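"""Overdispersed-gene selection and two-level Louvain graph clustering.

Clustering follows the conventional single-cell recipe: restrict to
overdispersed genes (coefficient-of-variation residuals above a rolling
mean-trend baseline, cell-cycle genes excluded first), log-normalize, reduce
to the top principal components, build a k-nearest-neighbor graph and run
Louvain community detection at a chosen resolution. Sub-clustering re-runs
the whole recipe on the cells of one main cluster with freshly selected
overdispersed genes, namespacing labels as ``main.sub``.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .io import CountMatrix, normalize_symbol
from .preprocess import cp10k, log_normalize

__all__ = ["ClusterParams", "select_overdispersed", "cluster_cells",
           "subcluster", "merge_or_split"]


@dataclass
class ClusterParams:
    """Graph-clustering knobs; defaults sit at the midpoints of the
    conventional working ranges (neighbors 5-25, resolution 0.8-1.5,
    top ~20 PCs)."""

    n_neighbors: int = 15
    n_pcs: int = 20
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5 <= self.n_neighbors <= 25):
            raise ValueError("n_neighbors must lie in [5, 25]")
        if not (0.8 <= self.resolution <= 1.5):
            raise ValueError("resolution must lie in [0.8, 1.5]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be positive")


def select_overdispersed(
    cm: CountMatrix,
    cc_gene_list: list[str] | None = None,
    n_top: int = 500,
    n_bins: int = 20,
    baseline_quantile: float = 25.0,
) -> list[str]:
    """Genes with the largest positive log-CV residual over the mean trend.

    Cell-cycle genes are removed first; per gene the mean and coefficient of
    variation are computed on depth-normalized counts; the log CV vs log mean
    trend is a rolling lower-quantile baseline (default 25th percentile) over
    ``n_bins`` mean-quantile bins and the top ``n_top`` residuals are
    returned. A lower quantile rather than the median keeps the baseline
    anchored to the non-variable bulk even in mean ranges where genuinely
    variable genes are locally abundant.
    """
    cc = {normalize_symbol(g) for g in (cc_gene_list or [])}
    keep = [i for i, g in enumerate(cm.gene_ids) if normalize_symbol(g) not in cc]

    norm = cp10k(cm)
    x = norm[keep, :]
    n = cm.n_cells
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = np.maximum(sq - mean ** 2, 0.0) * (n / max(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, 0.0)

    expressed = (mean > 0) & (cv > 0)
    idx = np.array(keep)[expressed]
    log_mean = np.log(mean[expressed])
    log_cv = np.log(cv[expressed])

    if len(idx) == 0:
        return []
    # rolling lower-quantile baseline over mean-quantile bins; keep at
    # least ~5 genes per bin so the quantile is meaningful
    order = np.argsort(log_mean, kind="stable")
    n_bins_eff = max(1, min(n_bins, len(order) // 5))
    bins = np.array_split(order, n_bins_eff)
    resid = np.empty_like(log_cv)
    for b in bins:
        resid[b] = log_cv[b] - np.percentile(log_cv[b], baseline_quantile)

    if n_top > len(idx):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(idx)} available genes; returning all"
        )
        n_top = len(idx)
    top = idx[np.argsort(-resid, kind="stable")[:n_top]]
    return [cm.gene_ids[i] for i in sorted(top)]


def _louvain(adj, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(adj, k=1).tocoo()
    g = igraph.Graph(n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    igraph.set_random_number_generator(random)  # restore default
    labels = np.asarray(part.membership)
    # relabel deterministically: 0 = largest community, ties by first member
    sizes = np.bincount(labels)
    first = np.full(sizes.size, labels.size)
    for i, l in enumerate(labels):
        first[l] = min(first[l], i)
    order = sorted(range(sizes.size), key=lambda l: (-sizes[l], first[l]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def cluster_cells(cm: CountMatrix, params: ClusterParams | None = None) -> np.ndarray:
    """Louvain cluster labels (0..C-1) for each cell of ``cm``.

    ``cm`` should already be restricted to the overdispersed genes; the
    pipeline is log-normalize, PCA, kNN graph, Louvain.
    """
    params = params or ClusterParams()
    if cm.n_cells < 2 * params.n_neighbors:
        raise ValueError(
            f"need at least {2 * params.n_neighbors} cells, got {cm.n_cells}"
        )
    x = np.asarray(log_normalize(cm).todense()).T  # cells x genes
    if np.allclose(x, x[0]):
        warnings.warn("all cells identical; returning a single cluster")
        return np.zeros(cm.n_cells, dtype=int)
    n_pcs = min(params.n_pcs, x.shape[0] - 1, x.shape[1])
    emb = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=params.seed).fit_transform(x)
    adj = kneighbors_graph(emb, params.n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize (union of neighborhoods)
    return _louvain(adj, params.resolution, params.seed)


def subcluster(
    cm: CountMatrix,
    labels: np.ndarray,
    target_main_label,
    params: ClusterParams | None = None,
    cc_gene_list: list[str] | None = None,
    n_top: int = 300,
) -> np.ndarray:
    """Re-cluster the cells of one main cluster; labels become ``main.sub``.

    Overdispersed genes are re-selected on the subset so sub-structure that
    is invisible atlas-wide can drive the split. Subsets too small to
    cluster are returned unchanged (single ``main.0`` subcluster).
    """
    params = params or ClusterParams()
    labels = np.asarray(labels)
    mask = labels == target_main_label
    if not mask.any():
        raise ValueError(f"label {target_main_label!r} not present")
    out = labels.astype(object).copy()
    sub_cm = cm.subset_cells(mask)
    if sub_cm.n_cells < 2 * params.n_neighbors:
        warnings.warn("subset too small to subcluster; left unchanged")
        out[mask] = f"{target_main_label}.0"
        return out
    genes = select_overdispersed(sub_cm, cc_gene_list, n_top=n_top)
    sub_labels = cluster_cells(sub_cm.subset_genes(genes), params)
    out[mask] = [f"{target_main_label}.{s}" for s in sub_labels]
    return out


def merge_or_split(labels: np.ndarray, merge_map: dict) -> np.ndarray:
    """Apply a relabeling map (old label -> new label) to cluster labels."""
    labels = np.asarray(labels)
    present = set(labels.tolist())
    unknown = set(merge_map) - present
    if unknown:
        raise ValueError(f"merge_map references absent labels: {sorted(map(str, unknown))}")
    return np.array([merge_map.get(l, l) for l in labels])
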