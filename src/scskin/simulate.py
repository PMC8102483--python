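"""Two-condition, multi-donor scRNA-seq count simulator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: K cell types with disjoint planted marker-gene sets, several donors
per condition, condition-responsive genes (including planted ligand genes in
designated sender types), doublets formed by summing two singlet profiles,
mitochondrial genes under the "MT-" prefix with a planted high-mito cell
subpopulation, and a tunable negative-binomial (gamma-Poisson) noise model.

Counts for gene g in cell i are NB with mean ``base_mean`` scaled by
``2**marker_log2fc`` when g is a marker of the cell's type, and additionally
by ``2**de_log2fc`` when g is a planted condition-response gene of that type
and the cell comes from the disease condition. Dispersion is ``phi`` in
``var = mu + phi * mu**2``.

Everything is keyed on an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CellMeta, CountMatrix

import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_atlas",
    "randomize_matrix",
    "rename_species",
    "simulate_ontology",
    "simulate_lr_database",
]

MITO_PREFIX = "MT-"


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults describe a compact two-condition, three-donors-per-condition
    atlas with 8 cell types, 30 markers per type at log2 fold change 3 and
    NB dispersion 0.5 — strongly separated types at desk scale.
    """

    n_types: int = 8
    genes: int = 2000
    # condition -> expected cells per type per donor; an int applies to all
    # types, a list of length n_types plants composition differences.
    cells_per_type_per_donor: dict = field(
        default_factory=lambda: {"control": 100 / 6, "disease": 100 / 6}
    )
    n_donors_per_condition: int = 3
    marker_genes_per_type: int = 30
    marker_log2fc: float = 3.0
    de_genes_per_type: int = 20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.5
    base_mean: float = 1.0
    # per-gene baseline means are lognormal around base_mean with this
    # log-sd, mimicking the heterogeneous expression levels of real genes;
    # planted marker/DE genes draw from the upper tail (>= base_mean) so
    # they stay detectable, as real marker genes are well expressed
    base_mean_sigma: float = 1.0
    doublet_rate: float = 0.0
    mito_gene_count: int = 10
    high_mito_cell_rate: float = 0.0
    mito_high_fraction: float = 0.25
    # sender type index -> number of planted upregulated ligand genes; these
    # are carved out of that type's planted DE-up genes and named LIG<t>_<j>.
    ligand_truth: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.genes < 1:
            raise ValueError("n_types and genes must be positive")
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must be in [0, 1)")
        if not (0 <= self.high_mito_cell_rate < 1):
            raise ValueError("high_mito_cell_rate must be in [0, 1)")
        needed = self.n_types * (self.marker_genes_per_type + self.de_genes_per_type)
        if needed + self.mito_gene_count > self.genes:
            raise ValueError(
                f"planted gene sets ({needed} + {self.mito_gene_count} mito) "
                f"exceed the gene budget ({self.genes})"
            )


@dataclass
class GroundTruth:
    """Planted truth per cell and per gene set, aligned to the barcodes."""

    true_type: np.ndarray          # str array, "type<k>" ("doublet" parents recorded)
    true_condition: np.ndarray     # str array
    is_doublet: np.ndarray         # bool
    doublet_parents: list          # (typeA, typeB) or None per cell
    is_high_mito: np.ndarray       # bool
    planted_markers: dict          # type name -> list of gene symbols
    planted_de: dict               # (type name, "up"/"down") -> list of gene symbols
    planted_ligands: dict          # sender type name -> list of ligand gene symbols


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + phi mu^2 (Poisson when phi == 0)."""
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def _type_name(k: int) -> str:
    return f"type{k}"


def simulate_atlas(cfg: SimConfig) -> tuple[CountMatrix, CellMeta, GroundTruth]:
    """Generate the synthetic atlas: counts, per-cell metadata, ground truth."""
    rng = np.random.default_rng(cfg.seed)
    K, G = cfg.n_types, cfg.genes

    # --- gene naming and planted sets -------------------------------------
    gene_ids = [f"GENE{j}" for j in range(G)]
    for j in range(cfg.mito_gene_count):
        gene_ids[G - cfg.mito_gene_count + j] = f"{MITO_PREFIX}G{j}"
    mito_idx = np.arange(G - cfg.mito_gene_count, G)

    planted_markers: dict[str, list[str]] = {}
    planted_de: dict[tuple[str, str], list[str]] = {}
    planted_ligands: dict[str, list[str]] = {}
    marker_idx = {}
    de_idx = {}
    cursor = 0
    for k in range(K):
        t = _type_name(k)
        m_idx = np.arange(cursor, cursor + cfg.marker_genes_per_type)
        cursor += cfg.marker_genes_per_type
        d_idx = np.arange(cursor, cursor + cfg.de_genes_per_type)
        cursor += cfg.de_genes_per_type
        marker_idx[k], de_idx[k] = m_idx, d_idx
        n_lig = int(cfg.ligand_truth.get(k, 0))
        if n_lig > cfg.de_genes_per_type:
            raise ValueError("ligand_truth exceeds de_genes_per_type")
        for j in range(n_lig):
            gene_ids[d_idx[j]] = f"LIG{k}_{j}"
        planted_markers[t] = [gene_ids[i] for i in m_idx]
        # first half of DE genes up in disease, second half down
        half = cfg.de_genes_per_type // 2
        # planted ligands must be upregulated: they sit at the front (up half)
        planted_de[(t, "up")] = [gene_ids[i] for i in d_idx[: max(half, n_lig)]]
        planted_de[(t, "down")] = [gene_ids[i] for i in d_idx[max(half, n_lig):]]
        planted_ligands[t] = [gene_ids[d_idx[j]] for j in range(n_lig)]

    # --- cell roster -------------------------------------------------------
    rows = []  # (type_k, condition, donor)
    for cond in ("control", "disease"):
        spec = cfg.cells_per_type_per_donor[cond]
        per_type = [spec] * K if np.isscalar(spec) else list(spec)
        if len(per_type) != K:
            raise ValueError("cells_per_type_per_donor list must have n_types entries")
        for d in range(cfg.n_donors_per_condition):
            donor = f"{'Ctrl' if cond == 'control' else 'Psor'}{d + 1}"
            for k in range(K):
                n = rng.poisson(per_type[k])
                rows += [(k, cond, donor)] * n
    n_singlets = len(rows)

    # --- per-cell mean construction ---------------------------------------
    if cfg.base_mean_sigma > 0:
        base = rng.lognormal(
            np.log(cfg.base_mean) - cfg.base_mean_sigma ** 2 / 2,
            cfg.base_mean_sigma, size=G,
        )
    else:
        base = np.full(G, cfg.base_mean)
    planted_idx = np.concatenate(
        [marker_idx[k] for k in range(K)] + [de_idx[k] for k in range(K)]
    ) if K else np.array([], dtype=int)
    base[planted_idx] = cfg.base_mean * np.exp(
        cfg.base_mean_sigma * np.abs(rng.standard_normal(planted_idx.size))
    )
    counts = np.zeros((G, n_singlets), dtype=np.int64)
    type_arr = np.array([_type_name(k) for k, _, _ in rows])
    cond_arr = np.array([c for _, c, _ in rows])
    donor_arr = np.array([d for _, _, d in rows])
    for i, (k, cond, _donor) in enumerate(rows):
        mu = base.copy()
        mu[marker_idx[k]] *= 2.0 ** cfg.marker_log2fc
        if cond == "disease":
            d_idx = de_idx[k]
            half = cfg.de_genes_per_type // 2
            n_lig = int(cfg.ligand_truth.get(k, 0))
            up = d_idx[: max(half, n_lig)]
            down = d_idx[max(half, n_lig):]
            mu[up] *= 2.0 ** cfg.de_log2fc
            mu[down] *= 2.0 ** (-cfg.de_log2fc)
        counts[:, i] = _nb_sample(rng, mu, cfg.nb_dispersion)

    # --- doublets: sum two singlet profiles from distinct types ------------
    n_doublets = int(round(cfg.doublet_rate * n_singlets / max(1 - cfg.doublet_rate, 1e-9)))
    doublet_cols = []
    doublet_parents: list = [None] * n_singlets
    for j in range(n_doublets):
        while True:
            a, b = rng.integers(0, n_singlets, size=2)
            if type_arr[a] != type_arr[b]:
                break
        doublet_cols.append(counts[:, a] + counts[:, b])
        doublet_parents.append((type_arr[a], type_arr[b]))
    if doublet_cols:
        counts = np.concatenate([counts, np.stack(doublet_cols, axis=1)], axis=1)
        type_arr = np.concatenate([type_arr, np.array(["doublet"] * n_doublets)])
        dbl_src = rng.integers(0, n_singlets, size=n_doublets)
        cond_arr = np.concatenate([cond_arr, cond_arr[dbl_src]])
        donor_arr = np.concatenate([donor_arr, donor_arr[dbl_src]])
    n_cells = counts.shape[1]
    is_doublet = np.zeros(n_cells, dtype=bool)
    is_doublet[n_singlets:] = True

    # --- planted high-mito cells -------------------------------------------
    is_high_mito = np.zeros(n_cells, dtype=bool)
    if cfg.high_mito_cell_rate > 0 and cfg.mito_gene_count > 0:
        n_high = int(round(cfg.high_mito_cell_rate * n_cells))
        chosen = rng.choice(n_cells, size=n_high, replace=False)
        is_high_mito[chosen] = True
        for i in chosen:
            non_mito_umi = counts[:, i].sum() - counts[mito_idx, i].sum()
            # inflate mito counts so the mito share lands near mito_high_fraction
            target_mito = cfg.mito_high_fraction / (1 - cfg.mito_high_fraction) * non_mito_umi
            mu = np.full(cfg.mito_gene_count, max(target_mito, 1.0) / cfg.mito_gene_count)
            counts[mito_idx, i] = _nb_sample(rng, mu, cfg.nb_dispersion)

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(sp.csr_matrix(counts), gene_ids, barcodes)
    meta = CellMeta(
        pd.DataFrame(
            {"sample_id": donor_arr, "condition": cond_arr}, index=barcodes
        )
    )
    truth = GroundTruth(
        true_type=type_arr,
        true_condition=cond_arr,
        is_doublet=is_doublet,
        doublet_parents=doublet_parents,
        is_high_mito=is_high_mito,
        planted_markers=planted_markers,
        planted_de=planted_de,
        planted_ligands=planted_ligands,
    )
    return cm, meta, truth


def randomize_matrix(cm: CountMatrix, seed: int) -> CountMatrix:
    """Negative-control randomization: permute each gene's counts across cells.

    Destroys cell identity while preserving each gene's value multiset
    exactly (hence per-gene mean, variance and detection rate).
    """
    rng = np.random.default_rng(seed)
    dense = cm.values.toarray()
    for g in range(dense.shape[0]):
        rng.shuffle(dense[g, :])
    return CountMatrix(sp.csr_matrix(dense), list(cm.gene_ids), list(cm.barcodes))


def rename_species(cm: CountMatrix, style: str = "mouse_case") -> CountMatrix:
    """Re-case gene symbols to emulate a second species (e.g. KRT14 -> Krt14)."""
    if style != "mouse_case":
        raise ValueError(f"unknown style {style!r}")
    renamed = [g[:1].upper() + g[1:].lower() if g else g for g in cm.gene_ids]
    return CountMatrix(cm.values.copy(), renamed, list(cm.barcodes))


def simulate_ontology(
    genes: list[str], n_terms: int = 30, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a small synthetic ontology DAG + gene annotations over ``genes``.

    Returns (edges, annotations) DataFrames in the package's TSV schema:
    edges (child, parent, child_name, namespace), annotations (gene, term).
    Terms form a rooted tree of depth 3 in the biological_process namespace;
    leaf terms are annotated with contiguous blocks of genes so that planted
    gene blocks enrich cleanly.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = terms[(i - 1) // 3]  # ternary tree
        edges.append((terms[i], parent, f"process_{i}", "biological_process"))
    leaves = [t for t in terms if t not in {e[1] for e in edges}]
    ann = []
    block = max(3, len(genes) // max(len(leaves), 1))
    for j, t in enumerate(leaves):
        lo = (j * block) % max(len(genes) - block, 1)
        for g in genes[lo: lo + block]:
            ann.append((g, t))
        extra = rng.choice(len(genes), size=2, replace=False)
        ann += [(genes[e], t) for e in extra]
    edges_df = pd.DataFrame(edges, columns=["child", "parent", "child_name", "namespace"])
    ann_df = pd.DataFrame(sorted(set(ann)), columns=["gene", "term"])
    return edges_df, ann_df


def simulate_lr_database(truth: GroundTruth, cm: CountMatrix,
                         n_background_pairs: int = 20, seed: int = 0) -> pd.DataFrame:
    """Build a ligand-receptor pair table containing the planted ligands.

    Each planted ligand is paired with a broadly expressed background gene as
    its receptor; extra background-background pairs pad the catalogue.
    Returns a DataFrame with columns ligand, receptor.
    """
    rng = np.random.default_rng(seed)
    planted = sorted({g for gl in truth.planted_ligands.values() for g in gl})
    background = [g for g in cm.gene_ids if g.startswith("GENE")]
    pairs = []
    for i, lig in enumerate(planted):
        pairs.append((lig, background[-(i + 1)]))
    for j in range(n_background_pairs):
        a, b = rng.choice(len(background) // 2, size=2, replace=False)
        pairs.append((background[a], background[b]))
    return pd.DataFrame(sorted(set(pairs)), columns=["ligand", "receptor"])
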