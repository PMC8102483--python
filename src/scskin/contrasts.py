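"""Condition contrasts: composition shifts, per-cluster differential
expression, and susceptibility-locus-to-cell-type mapping.

Composition: per cluster a 2x2 contingency table (in-cluster vs rest,
control vs disease) over pooled cells, two-sided Fisher exact test,
Benjamini-Hochberg FDR across clusters; significant at FDR < 0.01.

Differential expression: per cluster, genes detected in at least
``min_frac`` of the cluster's cells are tested control vs disease with a
two-sided Wilcoxon rank-sum on log-normalized expression; log2 fold changes
use a 0.01 pseudocount on condition means; BH FDR within cluster.

Locus mapping: each susceptibility-locus target gene is checked per cluster
for expression (detected in >= 10% of cells) and marker status; its
"significant existence" in a cluster means it is a significant marker there,
or expressed with an enrichment score above 1 at FPR < 0.1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import CellMeta, CountMatrix, normalize_symbol
from .preprocess import log_normalize

__all__ = ["composition_test", "differential_expression", "map_susceptibility_loci"]

DE_EPS = 0.01


def composition_test(labels, meta: CellMeta, barcodes: list[str],
                     fdr_cutoff: float = 0.01) -> pd.DataFrame:
    """Per-cluster composition contrast between the two conditions."""
    labels = np.asarray(labels)
    md = meta.aligned_to(barcodes)
    cond = md["condition"].to_numpy()
    c_ctrl, c_dis = meta.conditions
    n_ctrl_tot = int((cond == c_ctrl).sum())
    n_dis_tot = int((cond == c_dis).sum())
    if n_ctrl_tot == 0 or n_dis_tot == 0:
        raise ValueError("both conditions must have cells")

    rows = []
    for cl in sorted(set(labels.tolist()), key=str):
        in_cl = labels == cl
        a = int((in_cl & (cond == c_ctrl)).sum())
        b = int((in_cl & (cond == c_dis)).sum())
        table = [[a, n_ctrl_tot - a], [b, n_dis_tot - b]]
        _, p = fisher_exact(table, alternative="two-sided")
        p_ctrl, p_dis = a / n_ctrl_tot, b / n_dis_tot
        rows.append({
            "cluster": cl,
            "n_control": a, "n_disease": b,
            "proportion_control": p_ctrl, "proportion_disease": p_dis,
            "p_value": p,
            "direction": "up" if p_dis > p_ctrl else ("down" if p_dis < p_ctrl else "none"),
        })
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_significant"] = out["fdr"] < fdr_cutoff
    return out


def differential_expression(cm: CountMatrix, labels, meta: CellMeta,
                            min_frac: float = 0.1,
                            fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-cluster disease-vs-control DE table (Wilcoxon, BH within cluster)."""
    labels = np.asarray(labels)
    md = meta.aligned_to(cm.barcodes)
    cond = md["condition"].to_numpy()
    c_ctrl, c_dis = meta.conditions
    expr = np.asarray(log_normalize(cm).todense())
    detect = np.asarray((cm.values > 0).todense())

    frames = []
    for cl in sorted(set(labels.tolist()), key=str):
        in_cl = labels == cl
        ctrl = in_cl & (cond == c_ctrl)
        dis = in_cl & (cond == c_dis)
        if ctrl.sum() < 3 or dis.sum() < 3:
            warnings.warn(f"cluster {cl!r} skipped: fewer than 3 cells in a condition")
            continue
        eligible = np.flatnonzero(detect[:, in_cl].mean(axis=1) >= min_frac)
        if eligible.size == 0:
            continue
        xc, xd = expr[np.ix_(eligible, ctrl)], expr[np.ix_(eligible, dis)]
        mu_c, mu_d = xc.mean(axis=1), xd.mean(axis=1)
        with np.errstate(all="ignore"):
            _, p = mannwhitneyu(xd, xc, axis=1, alternative="two-sided")
        # a gene constant across all tested cells carries no signal
        const = (xc.std(axis=1) == 0) & (xd.std(axis=1) == 0) & (mu_c == mu_d)
        p = np.where(const, 1.0, p)
        log2fc = np.log2((mu_d + DE_EPS) / (mu_c + DE_EPS))
        fdr = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "cluster": cl,
            "gene": [cm.gene_ids[i] for i in eligible],
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(
                (fdr < fdr_cutoff) & (log2fc > 0), "up",
                np.where((fdr < fdr_cutoff) & (log2fc < 0), "down", "ns"),
            ),
        }))
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "gene", "log2fc", "p_value", "fdr", "direction"]
        )
    return pd.concat(frames, ignore_index=True)


def map_susceptibility_loci(locus_table: pd.DataFrame, markers: pd.DataFrame,
                            cm: CountMatrix, labels,
                            expr_frac: float = 0.1) -> pd.DataFrame:
    """Map locus target genes onto the cell types that express or mark them.

    Returns one row per (locus, target_gene, cluster) with expressed_flag,
    marker_flag and significant_existence; loci whose target is absent from
    the matrix or significant nowhere carry cluster = NaN rows flagged
    ``unassigned``.
    """
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()), key=str)
    gi = cm.gene_index()
    detect = np.asarray((cm.values > 0).todense())
    mk = markers.set_index(
        [markers["gene"].map(normalize_symbol), "cluster"]
    )

    rows = []
    for _, locus in locus_table.iterrows():
        gene = normalize_symbol(locus["target_gene"])
        gidx = gi.get(gene)
        assigned = False
        if gidx is not None:
            for cl in clusters:
                frac = detect[gidx, labels == cl].mean()
                expressed = bool(frac >= expr_frac)
                try:
                    row = mk.loc[(gene, cl)]
                    marker = bool(row["is_significant"])
                    enriched = bool(row["enrichment_score"] > 1 and row["fpr"] < 0.1)
                except KeyError:
                    marker = enriched = False
                sig = marker or (expressed and enriched)
                assigned |= sig
                rows.append({
                    "locus_id": locus["locus_id"], "target_gene": gene,
                    "cluster": cl, "expressed_flag": expressed,
                    "marker_flag": marker, "significant_existence": sig,
                    "unassigned": False,
                })
        rows.append({
            "locus_id": locus["locus_id"], "target_gene": gene,
            "cluster": np.nan, "expressed_flag": gidx is not None,
            "marker_flag": False, "significant_existence": False,
            "unassigned": not assigned,
        })
    return pd.DataFrame(rows)
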