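"""Marker-gene Enrichment Score with a permutation-based false positive rate.

For gene g and cluster c the enrichment score is the product of two ratios,
comparing the cells inside c against all other cells:

    E(g, c) = ((f_in + eps) / (f_out + eps)) * ((mu_in + eps) / (mu_out + eps))

where f is the detection fraction (fraction of cells with a nonzero raw
count) and mu the mean depth-normalized (counts-per-10k) expression; the
pseudocount eps (default 0.01) keeps cluster-exclusive genes large but
finite. Means stay on the linear scale so a true k-fold marker carries a
k-fold mu-ratio whatever its absolute expression; log transformation would
compress exactly the strongest markers. The fold change reported alongside
is log2((mu_in + eps) / (mu_out + eps)).

Significance is a permutation false positive rate: labels are shuffled
(cluster sizes preserved), E recomputed under each permutation, and
fpr(g, c) is the fraction of permuted scores at least as large as the
observed one. A marker is significant at fpr < 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix
from .preprocess import cp10k

__all__ = ["enrichment_scores", "marker_fpr", "significant_markers"]

EPS = 0.01
FPR_CUTOFF = 0.1


def _group_stats(detect, expr, onehot):
    """Per-cluster in/out detection fractions and mean expression.

    detect, expr: (genes, cells) arrays; onehot: (cells, clusters) float.
    Returns f_in, f_out, mu_in, mu_out of shape (genes, clusters).
    """
    n_in = onehot.sum(axis=0)
    n = onehot.shape[0]
    det_in = detect @ onehot
    ex_in = expr @ onehot
    det_tot = detect.sum(axis=1, keepdims=True)
    ex_tot = expr.sum(axis=1, keepdims=True)
    f_in = det_in / n_in
    mu_in = ex_in / n_in
    n_out = n - n_in
    f_out = (det_tot - det_in) / n_out
    mu_out = (ex_tot - ex_in) / n_out
    return f_in, f_out, mu_in, mu_out


def _scores_from_stats(f_in, f_out, mu_in, mu_out, eps=EPS):
    e = ((f_in + eps) / (f_out + eps)) * ((mu_in + eps) / (mu_out + eps))
    log2fc = np.log2((mu_in + eps) / (mu_out + eps))
    return e, log2fc


def _prepare(cm: CountMatrix, labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=str)
    if len(classes) < 2:
        raise ValueError("enrichment scores need at least 2 clusters")
    detect = np.asarray((cm.values > 0).todense(), dtype=float)
    expr = np.asarray(cp10k(cm).todense())
    return detect, expr, classes


def _onehot(labels, classes) -> np.ndarray:
    idx = {c: j for j, c in enumerate(classes)}
    oh = np.zeros((len(labels), len(classes)))
    oh[np.arange(len(labels)), [idx[l] for l in labels]] = 1.0
    return oh


def enrichment_scores(cm: CountMatrix, labels) -> pd.DataFrame:
    """MarkerTable skeleton: one row per (gene, cluster) with enrichment
    score and log2 fold change; FPR column left as NaN."""
    detect, expr, classes = _prepare(cm, labels)
    oh = _onehot(np.asarray(labels), classes)
    e, log2fc = _scores_from_stats(*_group_stats(detect, expr, oh))
    rows = []
    for j, c in enumerate(classes):
        rows.append(pd.DataFrame({
            "gene": cm.gene_ids,
            "cluster": c,
            "enrichment_score": e[:, j],
            "log2_fold_change": log2fc[:, j],
        }))
    out = pd.concat(rows, ignore_index=True)
    out["fpr"] = np.nan
    out["is_significant"] = False
    return out


def marker_fpr(
    cm: CountMatrix,
    labels,
    scores: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    fpr_cutoff: float = FPR_CUTOFF,
) -> pd.DataFrame:
    """Fill the permutation FPR and significance columns of the MarkerTable.

    The null preserves cluster sizes: each permutation shuffles the label
    vector and recomputes every E(g, c). fpr is the fraction of permuted
    scores >= observed (add-one corrected so 0 is never reported with
    finite permutations).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = np.asarray(labels)
    detect, expr, classes = _prepare(cm, labels)
    if scores is None:
        scores = enrichment_scores(cm, labels)
    obs = scores.pivot(index="gene", columns="cluster",
                       values="enrichment_score")
    obs = obs.loc[cm.gene_ids, classes].to_numpy()

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        oh = _onehot(perm_labels, classes)
        e, _ = _scores_from_stats(*_group_stats(detect, expr, oh))
        exceed += e >= obs
    fpr = (exceed + 1) / (n_perm + 1)

    fpr_df = pd.DataFrame(fpr, index=cm.gene_ids, columns=classes)
    out = scores.drop(columns=["fpr", "is_significant"], errors="ignore").copy()
    out["fpr"] = [
        fpr_df.at[g, c] for g, c in zip(out["gene"], out["cluster"])
    ]
    out["is_significant"] = out["fpr"] < fpr_cutoff
    return out


def significant_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Rows of a filled MarkerTable passing the FPR cutoff."""
    if markers["fpr"].isna().any():
        raise ValueError("MarkerTable has no FPR yet; run marker_fpr first")
    return markers[markers["is_significant"]].copy()
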