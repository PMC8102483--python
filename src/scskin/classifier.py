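"""Probabilistic cell-identity scoring with a small feed-forward network.

A feature panel is built from the significant markers of each cluster (top-k
by fold change). Cells, restricted to the panel and log-normalized then
per-gene standardized with training-set statistics, are classified by a
single-hidden-layer softmax network (64 ReLU units, cross-entropy loss,
Adam, 100 epochs) trained from a fixed seed. The softmax posterior over the
trained cell types is the cell's identity score vector; rows sum to 1.

Query matrices are matched to the panel by case-normalized gene symbols, so
a matrix with mouse-cased orthologous symbols (Krt14 vs KRT14) projects
through the model unchanged; missing panel genes are imputed as zero and the
missing fraction is reported.

The randomized negative control scores a per-gene permuted copy of the
training matrix with the trained model and reports the fraction of cells
still confidently assigned to their original cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import CountMatrix, normalize_symbol
from .preprocess import log_normalize
from .simulate import randomize_matrix

__all__ = [
    "FeaturePanel", "TrainConfig", "IdentityModel", "IdentityScores",
    "build_panel", "train", "score", "cross_validate",
    "randomized_control", "radar_coordinates",
]


@dataclass
class FeaturePanel:
    """Ordered marker-gene panel with the cluster each gene came from."""

    genes: list[str]
    source: dict  # cluster -> list of its contributed genes

    def __post_init__(self) -> None:
        if len(set(map(normalize_symbol, self.genes))) != len(self.genes):
            raise ValueError("panel genes must be unique")


@dataclass
class TrainConfig:
    """Network/optimizer knobs. Label smoothing and the small weight decay
    keep softmax confidence calibrated, so off-manifold inputs (e.g. the
    randomized negative control) do not receive confident assignments."""

    hidden_units: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 1e-3
    label_smoothing: float = 0.1
    seed: int = 0


@dataclass
class IdentityModel:
    panel: FeaturePanel
    class_labels: list
    weights: dict          # W1, b1, W2, b2
    train_config: TrainConfig
    feature_mean: np.ndarray = field(repr=False, default=None)
    feature_std: np.ndarray = field(repr=False, default=None)


@dataclass
class IdentityScores:
    """Cell x class posterior probabilities plus the argmax assignment."""

    probabilities: pd.DataFrame   # index barcodes, columns class labels
    missing_panel_fraction: float = 0.0

    @property
    def assigned_label(self) -> pd.Series:
        return self.probabilities.idxmax(axis=1)

    @property
    def assigned_prob(self) -> pd.Series:
        return self.probabilities.max(axis=1)


def build_panel(markers: pd.DataFrame, k_per_cluster: int = 30) -> FeaturePanel:
    """Top-k significant markers per cluster, ranked by log2 fold change.

    The union over clusters is deduplicated keeping the first contributing
    cluster; a cluster with no significant markers contributes nothing
    (with a warning).
    """
    if markers["fpr"].isna().any():
        raise ValueError("markers must have the FPR column filled")
    genes: list[str] = []
    seen: set[str] = set()
    source: dict = {}
    for cluster, grp in markers.groupby("cluster", sort=True):
        sig = grp[grp["is_significant"]].sort_values(
            ["log2_fold_change", "gene"], ascending=[False, True]
        )
        if sig.empty:
            warnings.warn(f"cluster {cluster!r} has no significant markers")
            source[cluster] = []
            continue
        contributed = []
        for g in sig["gene"].head(k_per_cluster):
            key = normalize_symbol(g)
            if key not in seen:
                seen.add(key)
                genes.append(g)
                contributed.append(g)
        source[cluster] = contributed
    return FeaturePanel(genes=genes, source=source)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights: dict, x: np.ndarray):
    h = np.maximum(x @ weights["W1"] + weights["b1"], 0.0)
    return h, _softmax(h @ weights["W2"] + weights["b2"])


def _panel_features(cm: CountMatrix, panel: FeaturePanel):
    """Log-normalized expression restricted to the panel, zero-filling
    panel genes absent from the matrix. Returns (cells x genes, missing_frac)."""
    gi = cm.gene_index()
    expr = np.asarray(log_normalize(cm).todense())
    x = np.zeros((cm.n_cells, len(panel.genes)))
    missing = 0
    for j, g in enumerate(panel.genes):
        i = gi.get(normalize_symbol(g))
        if i is None:
            missing += 1
        else:
            x[:, j] = expr[i, :]
    return x, missing / max(len(panel.genes), 1)


def train(cm: CountMatrix, labels, panel: FeaturePanel,
          cfg: TrainConfig | None = None) -> IdentityModel:
    """Fit the softmax network on panel features; deterministic given seed."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=str)
    for c in classes:
        n_c = int((labels == c).sum())
        if n_c < 10:
            raise ValueError(f"class {c!r} has only {n_c} cells (< 10)")
    y = np.array([classes.index(l) for l in labels])

    x, _ = _panel_features(cm, panel)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    x = (x - mean) / std

    rng = np.random.default_rng(cfg.seed)
    n_in, n_hid, n_out = x.shape[1], cfg.hidden_units, len(classes)
    weights = {
        "W1": rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_hid)),
        "b1": np.zeros(n_hid),
        "W2": rng.normal(0, np.sqrt(2.0 / n_hid), size=(n_hid, n_out)),
        "b2": np.zeros(n_out),
    }
    m = {k: np.zeros_like(v) for k, v in weights.items()}
    v = {k: np.zeros_like(w) for k, w in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = x.shape[0]
    ls = cfg.label_smoothing
    onehot = np.eye(n_out)[y] * (1 - ls) + ls / n_out
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            xb, yb = x[idx], onehot[idx]
            h, p = _forward(weights, xb)
            dz2 = (p - yb) / len(idx)
            grads = {
                "W2": h.T @ dz2 + cfg.weight_decay * weights["W2"],
                "b2": dz2.sum(axis=0),
            }
            dh = dz2 @ weights["W2"].T
            dh[h <= 0] = 0.0
            grads["W1"] = xb.T @ dh + cfg.weight_decay * weights["W1"]
            grads["b1"] = dh.sum(axis=0)
            step += 1
            for k in weights:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                weights[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return IdentityModel(
        panel=panel, class_labels=classes, weights=weights,
        train_config=cfg, feature_mean=mean, feature_std=std,
    )


def score(model: IdentityModel, cm_query: CountMatrix) -> IdentityScores:
    """Softmax posteriors of query cells over the model's cell types.

    Query genes are matched by case-normalized symbol; missing panel genes
    are zero-imputed. More than 50% missing is an error (insufficient
    overlap for a meaningful projection).
    """
    x, missing_frac = _panel_features(cm_query, model.panel)
    if missing_frac > 0.5:
        raise ValueError(
            f"{missing_frac:.0%} of panel genes missing from the query; "
            "insufficient overlap"
        )
    x = (x - model.feature_mean) / model.feature_std
    _, p = _forward(model.weights, x)
    probs = pd.DataFrame(p, index=cm_query.barcodes, columns=model.class_labels)
    return IdentityScores(probabilities=probs, missing_panel_fraction=missing_frac)


def cross_validate(cm: CountMatrix, labels, panel: FeaturePanel,
                   folds: int = 5, cfg: TrainConfig | None = None) -> dict:
    """Stratified k-fold CV; returns overall accuracy and per-class recall."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < folds]
    if not small.empty:
        warnings.warn(
            f"classes smaller than {folds} folds: {list(small.index)}; "
            "stratification will merge them opportunistically"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    correct = np.zeros(len(labels), dtype=bool)
    strat = pd.factorize(labels)[0]
    for tr, te in skf.split(np.zeros(len(labels)), strat):
        model = train(cm.subset_cells(tr), labels[tr], panel, cfg)
        sc = score(model, cm.subset_cells(te))
        correct[te] = sc.assigned_label.to_numpy() == labels[te].astype(object)
    per_class = {
        c: float(correct[labels == c].mean()) for c in sorted(set(labels.tolist()), key=str)
    }
    return {"overall_accuracy": float(correct.mean()), "per_class_recall": per_class}


def randomized_control(cm: CountMatrix, labels, model: IdentityModel,
                       assign_threshold: float = 0.5, seed: int = 0) -> float:
    """Fraction of per-gene-randomized cells still confidently assigned to
    their own cluster (posterior >= threshold AND argmax = original label).

    On an informative model this should collapse to ~0: randomization
    destroys cell identity while preserving per-gene statistics.
    """
    k = len(model.class_labels)
    if not (1.0 / k < assign_threshold <= 1.0):
        raise ValueError(f"assign_threshold must lie in (1/{k}, 1]")
    labels = np.asarray(labels)
    sc = score(model, randomize_matrix(cm, seed))
    hit = (
        (sc.assigned_prob.to_numpy() >= assign_threshold)
        & (sc.assigned_label.to_numpy() == labels.astype(object))
    )
    return float(hit.mean())


def radar_coordinates(scores: IdentityScores, class_order: list) -> pd.DataFrame:
    """2-D radar coordinates: classes anchored on the unit circle, each cell
    at the probability-weighted mean of the anchor vertices."""
    if sorted(map(str, class_order)) != sorted(map(str, scores.probabilities.columns)):
        raise ValueError("class_order must be a permutation of the score classes")
    k = len(class_order)
    angles = 2 * np.pi * np.arange(k) / k
    anchors = np.column_stack([np.cos(angles), np.sin(angles)])
    p = scores.probabilities[class_order].to_numpy()
    xy = p @ anchors
    return pd.DataFrame(xy, index=scores.probabilities.index, columns=["x", "y"])
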