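"""Shared data model and readers/writers for the on-disk formats the pipeline touches.

The central container is :class:`CountMatrix`: a sparse gene x cell matrix of
non-negative integer UMI counts with gene symbols as row labels and cell
barcodes as column labels. Counts stay sparse; densification happens only
inside small per-cluster computations downstream.

Gene symbols are compared case-insensitively throughout the package (uppercase
for comparison, original casing preserved on output) so that human and mouse
symbols for 1:1 same-name orthologs (KRT14 / Krt14) match without an ortholog
table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellMeta",
    "LRDatabase",
    "normalize_symbol",
    "read_mtx",
    "write_mtx",
    "read_cell_meta",
    "write_cell_meta",
    "read_lr_database",
    "read_locus_table",
]


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol for comparison (uppercase, stripped)."""
    return symbol.strip().upper()


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        ``(n_genes, n_cells)`` sparse matrix (stored CSR) of counts.
    gene_ids
        Ordered gene symbols, unique after case-normalization.
    barcodes
        Ordered unique cell identifiers.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != row count {n_genes}"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcodes length {len(self.barcodes)} != column count {n_cells}"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts are not allowed")
        norm = [normalize_symbol(g) for g in self.gene_ids]
        if len(set(norm)) != len(norm):
            seen: dict[str, str] = {}
            for orig, n in zip(self.gene_ids, norm):
                if n in seen:
                    raise ValueError(
                        f"gene symbols {seen[n]!r} and {orig!r} collide after "
                        f"case-normalization ({n!r})"
                    )
                seen[n] = orig
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        """Map case-normalized symbol -> row index."""
        return {normalize_symbol(g): i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, mask_or_indices) -> "CountMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.barcodes[i] for i in idx],
        )

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        gi = self.gene_index()
        idx = [gi[normalize_symbol(g)] for g in genes]
        return CountMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            self.barcodes,
        )


@dataclass
class CellMeta:
    """Per-cell metadata: donor of origin and disease condition.

    ``table`` is indexed by barcode with columns ``sample_id`` and
    ``condition`` (a declared two-level set, by convention
    ``{"control", "disease"}``) plus any open extra columns.
    """

    table: pd.DataFrame
    conditions: tuple[str, str] = ("control", "disease")

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("barcodes in cell metadata must be unique")
        for col in ("sample_id", "condition"):
            if col not in self.table.columns:
                raise ValueError(f"cell metadata missing required column {col!r}")
        bad = set(self.table["condition"]) - set(self.conditions)
        if bad:
            raise ValueError(
                f"conditions {sorted(bad)} not in declared set {self.conditions}"
            )

    def aligned_to(self, barcodes: list[str]) -> pd.DataFrame:
        missing = [b for b in barcodes if b not in self.table.index]
        if missing:
            raise KeyError(
                f"{len(missing)} barcodes missing from metadata, e.g. {missing[:3]}"
            )
        return self.table.loc[barcodes]


@dataclass
class LRDatabase:
    """Catalogue of (ligand, receptor) gene-symbol pairs (case-normalized)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        cleaned = []
        for lig, rec in self.pairs:
            lig, rec = normalize_symbol(lig), normalize_symbol(rec)
            if not lig or not rec:
                raise ValueError("ligand and receptor symbols must be non-empty")
            if (lig, rec) not in seen:
                seen.add((lig, rec))
                cleaned.append((lig, rec))
        self.pairs = cleaned

    @property
    def ligands(self) -> set[str]:
        return {l for l, _ in self.pairs}

    @property
    def receptors(self) -> set[str]:
        return {r for _, r in self.pairs}


def _read_lines(path: str | os.PathLike, symbol_col: int | None = None) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if symbol_col is not None and len(fields) > 1:
                out.append(fields[symbol_col])
            else:
                out.append(fields[0])
    return out


def read_mtx(
    matrix_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet into a :class:`CountMatrix`.

    The gene file may carry 1-3 tab-separated columns (id, symbol, type); the
    symbol column (second when present) is used. On-disk orientation is
    inferred: the matrix is transposed if its rows match the barcode file and
    its columns the gene file. The result always has genes as rows.
    """
    mat = scipy.io.mmread(os.fspath(matrix_path))
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.tocoo().data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("matrix contains non-integer values")
        mat = mat.astype(np.int64)
    genes = _read_lines(genes_path, symbol_col=1)
    barcodes = _read_lines(barcodes_path)
    n_rows, n_cols = mat.shape
    if n_rows == len(genes) and n_cols == len(barcodes):
        pass
    elif n_rows == len(barcodes) and n_cols == len(genes) and n_rows != n_cols:
        mat = mat.T
    else:
        raise ValueError(
            "dimension mismatch between matrix and side files: matrix is "
            f"{n_rows}x{n_cols}, gene file has {len(genes)} entries, barcode "
            f"file has {len(barcodes)} entries"
        )
    return CountMatrix(sp.csr_matrix(mat), genes, barcodes)


def write_mtx(cm: CountMatrix, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``; round-trips exactly."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], cm.values.tocoo(), field="integer")
    with open(paths["genes"], "w", encoding="utf-8") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(paths["barcodes"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(cm.barcodes) + ("\n" if cm.barcodes else ""))
    return paths


def read_cell_meta(path: str | os.PathLike,
                   conditions: tuple[str, str] = ("control", "disease")) -> CellMeta:
    """Read a tab-delimited metadata table with columns barcode, sample_id, condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns:
        raise ValueError("cell metadata must have a 'barcode' column")
    return CellMeta(df.set_index("barcode"), conditions=conditions)


def write_cell_meta(meta: CellMeta, path: str | os.PathLike) -> None:
    meta.table.rename_axis("barcode").reset_index().to_csv(path, sep="\t", index=False)


def read_lr_database(path: str | os.PathLike) -> LRDatabase:
    """Read a ligand-receptor pair TSV with header columns ``ligand``, ``receptor``.

    Duplicate pairs are collapsed and symbols are case-normalized (uppercase).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"ligand-receptor table missing column {col!r}")
    return LRDatabase(list(zip(df["ligand"], df["receptor"])))


def read_locus_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a susceptibility-locus table with columns ``locus_id``, ``target_gene``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("locus_id", "target_gene"):
        if col not in df.columns:
            raise ValueError(f"locus table missing column {col!r}")
    df["target_gene"] = df["target_gene"].map(normalize_symbol)
    return df
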