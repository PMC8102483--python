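"""GO-bioprocess enrichment over a user-supplied ontology DAG.

The ontology arrives as two TSVs: an edge table (child term -> parent term,
``is_a``) and a gene-to-term annotation table. Annotations are propagated
upward (a gene annotated to a term is annotated to all its ancestors) before
testing. Per-term enrichment of a gene set against a background uses the
hypergeometric upper tail; BH FDR across tested terms (term size >= 3 in the
background); significant at FDR < 0.05. For multilayer plotting, the
subgraph of significant terms plus their ancestor paths to the root is
extracted, flagging "terminal" terms (significant with no significant
descendant).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import normalize_symbol

__all__ = ["Ontology", "load_ontology", "propagate_annotations", "enrich",
           "significant_subgraph"]


@dataclass
class Ontology:
    """Term DAG plus gene annotations.

    ``graph`` holds one node per term (attributes ``name``, ``namespace``)
    and an edge child -> parent for each is_a relation; ``annotations`` maps
    case-normalized gene symbol -> set of term ids.
    """

    graph: nx.DiGraph
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology edges contain a cycle: {cycle}")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable child->parent from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def term_genes(self) -> dict:
        """term -> set of annotated genes (as stored; propagate first)."""
        out: dict = {t: set() for t in self.graph.nodes}
        for gene, terms in self.annotations.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


def load_ontology(edges_path: str | os.PathLike,
                  annotations_path: str | os.PathLike,
                  namespace: str | None = "biological_process") -> Ontology:
    """Read the two-TSV ontology (edges: child, parent[, child_name,
    namespace]; annotations: gene, term), keeping one namespace."""
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
    for col in ("child", "parent"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    for col in ("gene", "term"):
        if col not in ann.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    g = nx.DiGraph()
    for _, row in edges.iterrows():
        ns = row.get("namespace", namespace)
        if namespace is not None and ns is not None and ns != namespace:
            continue
        g.add_edge(row["child"], row["parent"])
        g.nodes[row["child"]]["name"] = row.get("child_name", row["child"])
    annotations: dict = {}
    for _, row in ann.iterrows():
        if row["term"] in g:
            annotations.setdefault(normalize_symbol(row["gene"]), set()).add(row["term"])
    return Ontology(graph=g, annotations=annotations)


def propagate_annotations(ont: Ontology) -> Ontology:
    """Close annotations upward: gene on a term implies gene on its ancestors.

    Idempotent; the input is not modified.
    """
    anc_cache = {t: ont.ancestors(t) for t in ont.graph.nodes}
    closed: dict = {}
    for gene, terms in ont.annotations.items():
        full = set(terms)
        for t in terms:
            full |= anc_cache.get(t, set())
        closed[gene] = full
    return Ontology(graph=ont.graph.copy(), annotations=closed)


def enrich(gene_set, background, ont: Ontology,
           min_term_size: int = 3, fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``gene_set`` within ``background``.

    Per term with K annotated background genes: p = P(X >= k) for X
    hypergeometric(N, K, n), with k hits in the set, n the set size, N the
    background size. Terms with K < ``min_term_size`` are not tested.
    """
    gene_set = {normalize_symbol(g) for g in gene_set}
    background = {normalize_symbol(g) for g in background}
    if not gene_set:
        raise ValueError("gene_set is empty")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    n, N = len(gene_set), len(background)
    rows = []
    for term, genes in sorted(ont.term_genes().items()):
        bg_genes = {normalize_symbol(g) for g in genes} & background
        K = len(bg_genes)
        if K < min_term_size:
            continue
        k = len(bg_genes & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["is_significant"] = []
        return out
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_significant"] = out["fdr"] < fdr_cutoff
    return out


def significant_subgraph(results: pd.DataFrame, ont: Ontology) -> nx.DiGraph:
    """Induced subgraph of significant terms plus their root paths.

    Node attribute ``significant`` marks tested-significant terms and
    ``terminal`` marks significant terms with no significant descendant
    (i.e. the most specific enriched processes).
    """
    sig = set(results.loc[results["is_significant"], "term"]) if len(results) else set()
    keep = set(sig)
    for t in sig:
        keep |= ont.ancestors(t)
    sub = ont.graph.subgraph(keep).copy()
    # a term's ontology descendants are its graph *ancestors* (edges child->parent)
    for t in sub.nodes:
        child_terms = nx.ancestors(ont.graph, t)
        sub.nodes[t]["significant"] = t in sig
        sub.nodes[t]["terminal"] = t in sig and not (child_terms & sig)
    return sub
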