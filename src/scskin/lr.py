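"""Modified ligand-receptor analysis: active/total interaction ratio scoring.

Instead of regression-based ligand-activity scoring, interactions are
counted. For a sender cell type, candidate ligands are its disease-
upregulated genes intersected with the catalogue's ligands; for a receiver,
eligible receptors are catalogue receptors detected in at least ``expr_frac``
of the receiver's disease cells and not significantly downregulated
("constant or upregulated" expression). For each ordered (sender, receiver)
pair the total interaction events are the catalogue pairs whose ligand is
detected in the sender and whose receptor is eligible in the receiver; the
active events are the subset whose ligand is upregulated in the sender. The
score is active/total, and the top interactions are kept either at a fixed
ratio cutoff (default 0.35) or at the knee of the sorted ratio curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellMeta, CountMatrix, LRDatabase, normalize_symbol

__all__ = [
    "InteractionScore", "select_ligands", "select_receptors",
    "score_interactions", "select_top", "export_chord", "export_sankey",
]


@dataclass
class InteractionScore:
    sender: object
    receiver: object
    active_events: int
    total_events: int
    active_pairs: list = field(default_factory=list)
    total_pairs: list = field(default_factory=list)

    @property
    def ratio(self) -> float:
        return self.active_events / self.total_events

    @property
    def autocrine(self) -> bool:
        return self.sender == self.receiver


def _detection_fraction(cm: CountMatrix, mask: np.ndarray) -> np.ndarray:
    sub = cm.values[:, np.flatnonzero(mask)]
    if sub.shape[1] == 0:
        return np.zeros(cm.n_genes)
    return np.asarray((sub > 0).mean(axis=1)).ravel()


def select_ligands(de: pd.DataFrame, lrdb: LRDatabase,
                   fdr_cutoff: float = 0.05) -> dict:
    """Per-sender upregulated ligand sets: disease-upregulated genes
    (fdr < cutoff, log2fc > 0) intersected with catalogue ligands."""
    ligs = lrdb.ligands
    out: dict = {}
    for cl, grp in de.groupby("cluster", sort=True):
        up = grp[(grp["fdr"] < fdr_cutoff) & (grp["log2fc"] > 0)]
        out[cl] = {normalize_symbol(g) for g in up["gene"]} & ligs
    return out


def select_receptors(cm: CountMatrix, labels, de: pd.DataFrame,
                     lrdb: LRDatabase, meta: CellMeta | None = None,
                     expr_frac: float = 0.10,
                     fdr_cutoff: float = 0.05) -> dict:
    """Per-receiver eligible receptor sets ("constant or upregulated"):
    catalogue receptors detected in >= expr_frac of the receiver's
    disease-condition cells and not significantly downregulated."""
    labels = np.asarray(labels)
    recs = lrdb.receptors
    gi = cm.gene_index()
    if meta is not None:
        cond = meta.aligned_to(cm.barcodes)["condition"].to_numpy()
        disease_mask = cond == meta.conditions[1]
    else:
        disease_mask = np.ones(cm.n_cells, dtype=bool)
    out: dict = {}
    for cl in sorted(set(labels.tolist()), key=str):
        frac = _detection_fraction(cm, (labels == cl) & disease_mask)
        grp = de[de["cluster"] == cl]
        down = {
            normalize_symbol(g)
            for g in grp.loc[(grp["fdr"] < fdr_cutoff) & (grp["log2fc"] < 0), "gene"]
        }
        chosen = set()
        for r in recs:
            i = gi.get(r)
            if i is not None and frac[i] >= expr_frac and r not in down:
                chosen.add(r)
        out[cl] = chosen
    return out


def score_interactions(ligand_sets: dict, receptor_sets: dict,
                       cm: CountMatrix, labels, lrdb: LRDatabase,
                       meta: CellMeta | None = None,
                       expr_frac: float = 0.10,
                       denominator: str = "expressed") -> list[InteractionScore]:
    """Active/total ratio for every ordered (sender, receiver) type pair.

    ``denominator='expressed'`` counts only biologically possible events
    (ligand detected in the sender, receptor eligible in the receiver);
    ``denominator='all'`` counts every catalogue pair whose receptor is
    eligible. Pairs with zero total events are omitted.
    """
    if denominator not in ("expressed", "all"):
        raise ValueError("denominator must be 'expressed' or 'all'")
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()), key=str)
    gi = cm.gene_index()
    if meta is not None:
        cond = meta.aligned_to(cm.barcodes)["condition"].to_numpy()
        disease_mask = cond == meta.conditions[1]
    else:
        disease_mask = np.ones(cm.n_cells, dtype=bool)
    sender_frac = {
        cl: _detection_fraction(cm, (labels == cl) & disease_mask) for cl in clusters
    }
    scores = []
    for s in clusters:
        up = ligand_sets.get(s, set())
        frac = sender_frac[s]
        for r in clusters:
            eligible_recs = receptor_sets.get(r, set())
            total_pairs, active_pairs = [], []
            for lig, rec in lrdb.pairs:
                if rec not in eligible_recs:
                    continue
                i = gi.get(lig)
                lig_expressed = i is not None and frac[i] >= expr_frac
                if denominator == "expressed" and not lig_expressed:
                    continue
                total_pairs.append((lig, rec))
                if lig in up:
                    active_pairs.append((lig, rec))
            if total_pairs:
                scores.append(InteractionScore(
                    sender=s, receiver=r,
                    active_events=len(active_pairs),
                    total_events=len(total_pairs),
                    active_pairs=sorted(active_pairs),
                    total_pairs=sorted(total_pairs),
                ))
    return scores


def select_top(scores: list[InteractionScore], mode: str = "fixed",
               fixed_cutoff: float = 0.35) -> tuple[list[InteractionScore], float]:
    """Keep the top interactions; returns (kept, cutoff used).

    ``fixed`` keeps ratio >= fixed_cutoff. ``knee`` sorts ratios descending
    and cuts at the point of maximum perpendicular distance to the chord
    from the first to the last point, falling back to the fixed cutoff when
    fewer than 3 scores exist or the curve is flat.
    """
    if mode not in ("fixed", "knee"):
        raise ValueError("mode must be 'fixed' or 'knee'")
    ordered = sorted(scores, key=lambda s: (-s.ratio, str(s.sender), str(s.receiver)))
    if mode == "fixed" or len(ordered) < 3:
        if mode == "knee" and len(ordered) < 3:
            warnings.warn("fewer than 3 scores; knee undefined, using fixed cutoff")
        kept = [s for s in ordered if s.ratio >= fixed_cutoff]
        return kept, fixed_cutoff
    y = np.array([s.ratio for s in ordered])
    if np.allclose(y, y[0]):
        warnings.warn("all ratios equal; knee undefined, using fixed cutoff")
        kept = [s for s in ordered if s.ratio >= fixed_cutoff]
        return kept, fixed_cutoff
    x = np.arange(len(y), dtype=float)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, y]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    knee = int(np.argmax(dist))
    kept = ordered[: knee + 1]
    return kept, float(y[knee])


def export_chord(scores: list[InteractionScore]) -> pd.DataFrame:
    """Chord-plot table: one row per (sender, receiver) with ratio and counts."""
    rows = [{
        "sender": s.sender, "receiver": s.receiver,
        "ratio": s.ratio, "active_events": s.active_events,
        "total_events": s.total_events, "autocrine": s.autocrine,
    } for s in scores]
    df = pd.DataFrame(rows, columns=["sender", "receiver", "ratio",
                                     "active_events", "total_events", "autocrine"])
    return df.sort_values(["sender", "receiver"], key=lambda s: s.astype(str),
                          ignore_index=True)


def export_sankey(scores: list[InteractionScore]) -> pd.DataFrame:
    """Sankey flow table: one row per active (ligand, receptor) pair."""
    rows = []
    for s in scores:
        for lig, rec in s.active_pairs:
            rows.append({"sender": s.sender, "receiver": s.receiver,
                         "ligand": lig, "receptor": rec})
    df = pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor"])
    return df.sort_values(["sender", "receiver", "ligand", "receptor"],
                          key=lambda s: s.astype(str), ignore_index=True)
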