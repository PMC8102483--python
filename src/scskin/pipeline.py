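"""End-to-end orchestration: qc -> cluster -> markers -> classifier ->
contrasts -> go -> lr, driven by a single config with one seed.

Every stage writes a TSV under the output directory and the run closes with
a ``manifest.json`` recording the package version, seed, parameters and
per-stage row counts. Re-running with the same config reproduces
byte-identical stage outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import TrainConfig, build_panel, cross_validate, score, train
from .cluster import ClusterParams, cluster_cells, select_overdispersed
from .contrasts import (composition_test, differential_expression,
                        map_susceptibility_loci)
from .go import enrich, load_ontology, propagate_annotations
from .io import (read_cell_meta, read_locus_table, read_lr_database, read_mtx)
from .lr import (export_chord, export_sankey, score_interactions,
                 select_ligands, select_receptors, select_top)
from .markers import enrichment_scores, marker_fpr
from .qc import QCThresholds, compute_cell_qc, filter_cells, predict_doublets

logger = logging.getLogger("scskin")

__all__ = ["PipelineConfig", "run_all"]

STAGES = ["qc", "cluster", "markers", "classifier", "contrasts", "go", "lr"]


@dataclass
class PipelineConfig:
    """Paths plus per-stage knobs; the seed feeds every stochastic stage."""

    matrix: str = ""
    genes: str = ""
    barcodes: str = ""
    meta: str = ""
    lrdb: str = ""
    loci: str = ""
    go_edges: str = ""
    go_annotations: str = ""
    out_dir: str = "pipeline_out"
    seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    mito_prefix: str = "MT-"
    cluster: ClusterParams = field(default_factory=ClusterParams)
    n_overdispersed: int = 500
    cc_genes: list = field(default_factory=list)
    n_perm: int = 200
    panel_k: int = 30
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 0          # 0 skips cross-validation
    de_min_frac: float = 0.1
    lr_cutoff: float = 0.35
    lr_mode: str = "fixed"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("qc", QCThresholds), ("cluster", ClusterParams),
                         ("train", TrainConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        required = {"matrix": self.matrix, "genes": self.genes,
                    "barcodes": self.barcodes, "meta": self.meta,
                    "lrdb": self.lrdb, "go_edges": self.go_edges,
                    "go_annotations": self.go_annotations}
        if self.loci:
            required["loci"] = self.loci
        missing = [k for k, p in required.items() if not p or not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(
                f"config paths missing or nonexistent: {missing}"
            )


def _stage(manifest, name, t0, **counts):
    dt = time.perf_counter() - t0
    logger.info("stage %-10s done in %.2fs %s", name, dt, counts)
    manifest["stages"].append({"name": name, **counts})


def run_all(cfg: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute every stage in order and write outputs + manifest.

    Returns the manifest dict. ``dry_run`` validates the config (all input
    paths exist) without computing anything.
    """
    cfg.validate()
    if dry_run:
        return {"dry_run": True, "stages": []}
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "qc": asdict(cfg.qc), "cluster": asdict(cfg.cluster),
            "train": asdict(cfg.train), "n_perm": cfg.n_perm,
            "panel_k": cfg.panel_k, "de_min_frac": cfg.de_min_frac,
            "lr_cutoff": cfg.lr_cutoff, "lr_mode": cfg.lr_mode,
            "n_overdispersed": cfg.n_overdispersed,
        },
        "stages": [],
    }
    out = lambda name: os.path.join(cfg.out_dir, name)

    cm = read_mtx(cfg.matrix, cfg.genes, cfg.barcodes)
    meta = read_cell_meta(cfg.meta)

    # --- qc ---------------------------------------------------------------
    t0 = time.perf_counter()
    qc_table = compute_cell_qc(cm, cfg.mito_prefix)
    _, doublet_mask = predict_doublets(
        cm, cfg.qc.expected_doublet_rate, seed=cfg.seed
    )
    kept = filter_cells(qc_table, cfg.qc, doublet_mask)
    qc_table.assign(is_doublet=doublet_mask,
                    kept=qc_table.index.isin(kept)).rename_axis("barcode") \
        .to_csv(out("qc.tsv"), sep="\t")
    keep_idx = [i for i, b in enumerate(cm.barcodes) if b in set(kept)]
    cm = cm.subset_cells(np.array(keep_idx))
    _stage(manifest, "qc", t0, n_cells_in=len(qc_table), n_cells_kept=len(kept))

    # --- cluster ----------------------------------------------------------
    t0 = time.perf_counter()
    od = select_overdispersed(cm, cfg.cc_genes, n_top=cfg.n_overdispersed)
    labels = cluster_cells(cm.subset_genes(od), cfg.cluster)
    pd.DataFrame({"barcode": cm.barcodes, "cluster": labels}) \
        .to_csv(out("labels.tsv"), sep="\t", index=False)
    _stage(manifest, "cluster", t0, n_clusters=int(len(set(labels.tolist()))),
           n_overdispersed=len(od))

    # --- markers ----------------------------------------------------------
    t0 = time.perf_counter()
    mk = marker_fpr(cm, labels, enrichment_scores(cm, labels),
                    n_perm=cfg.n_perm, seed=cfg.seed)
    mk.to_csv(out("markers.tsv"), sep="\t", index=False)
    _stage(manifest, "markers", t0,
           n_significant=int(mk["is_significant"].sum()))

    # --- classifier -------------------------------------------------------
    t0 = time.perf_counter()
    panel = build_panel(mk, k_per_cluster=cfg.panel_k)
    model = train(cm, labels, panel, cfg.train)
    sc = score(model, cm)
    sc.probabilities.assign(
        assigned_label=sc.assigned_label, assigned_prob=sc.assigned_prob
    ).rename_axis("barcode").to_csv(out("identity_scores.tsv"), sep="\t")
    cv_acc = None
    if cfg.cv_folds >= 2:
        cv_acc = cross_validate(cm, labels, panel, cfg.cv_folds, cfg.train)[
            "overall_accuracy"]
    _stage(manifest, "classifier", t0, panel_size=len(panel.genes),
           cv_accuracy=cv_acc)

    # --- contrasts --------------------------------------------------------
    t0 = time.perf_counter()
    comp = composition_test(labels, meta, cm.barcodes)
    comp.to_csv(out("composition.tsv"), sep="\t", index=False)
    de = differential_expression(cm, labels, meta, min_frac=cfg.de_min_frac)
    de.to_csv(out("de.tsv"), sep="\t", index=False)
    n_loci_assigned = None
    if cfg.loci:
        loci = map_susceptibility_loci(read_locus_table(cfg.loci), mk, cm, labels)
        loci.to_csv(out("loci.tsv"), sep="\t", index=False)
        summary = loci[loci["cluster"].isna()]
        n_loci_assigned = int((~summary["unassigned"]).sum())
    _stage(manifest, "contrasts", t0,
           n_significant_composition=int(comp["is_significant"].sum()),
           n_de_up=int((de["direction"] == "up").sum()),
           n_loci_assigned=n_loci_assigned)

    # --- go ---------------------------------------------------------------
    t0 = time.perf_counter()
    ont = propagate_annotations(load_ontology(cfg.go_edges, cfg.go_annotations))
    background = {g for g in cm.gene_ids}
    frames = []
    for cl, grp in de.groupby("cluster", sort=True):
        up = set(grp.loc[grp["direction"] == "up", "gene"])
        if not up:
            continue
        res = enrich(up, background, ont)
        res.insert(0, "cluster", cl)
        frames.append(res)
    go_res = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["cluster", "term", "k", "K", "n", "N",
                                         "p_value", "fdr", "is_significant"]))
    go_res.to_csv(out("go.tsv"), sep="\t", index=False)
    _stage(manifest, "go", t0,
           n_significant_terms=int(go_res["is_significant"].sum())
           if len(go_res) else 0)

    # --- lr ---------------------------------------------------------------
    t0 = time.perf_counter()
    lrdb = read_lr_database(cfg.lrdb)
    ligand_sets = select_ligands(de, lrdb)
    receptor_sets = select_receptors(cm, labels, de, lrdb, meta)
    scores = score_interactions(ligand_sets, receptor_sets, cm, labels, lrdb, meta)
    top, cutoff = select_top(scores, mode=cfg.lr_mode, fixed_cutoff=cfg.lr_cutoff)
    export_chord(scores).to_csv(out("lr_chord.tsv"), sep="\t", index=False)
    export_chord(top).to_csv(out("lr_top.tsv"), sep="\t", index=False)
    export_sankey(top).to_csv(out("lr_sankey.tsv"), sep="\t", index=False)
    _stage(manifest, "lr", t0, n_interactions=len(scores),
           n_top=len(top), cutoff=cutoff)

    with open(out("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
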