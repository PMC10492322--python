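"""Spearman-correlation minimum spanning trees over gene (or module) vectors.

A complete graph is built over a chosen gene set: each edge carries the
Spearman rank correlation of the two expression vectors, its two-sided
p-value, and an MST cost of ``1 - |rho|`` so that strongly correlated pairs
sit on short edges.  The minimum spanning tree extracts the backbone of the
correlation structure.  Nodes carry differential-expression annotations
(-log10 p and fold change) for display; edge display width is -log10 of the
Spearman p-value.  Module-level trees reuse the same code path with
module-score vectors in place of genes.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .modscore import ExpressionDataset

__all__ = [
    "spearman_edges",
    "annotate_nodes",
    "minimum_spanning_tree",
    "correlation_mst",
]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def spearman_edges(
    dataset: ExpressionDataset,
    gene_ids: list[str],
    sample_labels: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs Spearman correlations over the selected genes.

    ``sample_labels`` restricts the correlation to samples of those groups
    (default: all samples).  Returns an edge table with columns ``node_a,
    node_b, rho, p, weight`` where ``weight = 1 - |rho|``; a constant gene
    vector makes rho undefined and is recorded as rho 0 / weight 1 with a
    warning.  Node pairs are in lexicographic order.
    """
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes")
    if sample_labels is None:
        cols = np.arange(dataset.n_samples)
    else:
        cols = np.concatenate(
            [dataset.group_columns(lab) for lab in sample_labels]
        )
    if cols.size < 3:
        raise ValueError("need at least 3 samples for correlation")
    pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        raise KeyError(f"genes not in dataset: {missing}")
    vectors = {g: dataset.values[pos[g], cols] for g in gene_ids}
    constant = {g for g, v in vectors.items() if np.ptp(v) == 0}
    if constant:
        warnings.warn(
            f"constant expression vector(s) {sorted(constant)}: "
            "rho recorded as 0, weight 1",
            stacklevel=2,
        )
    rows = []
    for a, b in itertools.combinations(sorted(gene_ids), 2):
        if a in constant or b in constant:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(vectors[a], vectors[b])
            rho = float(rho)
            p = float(max(p, np.nextafter(0, 1)))
        rows.append(
            {"node_a": a, "node_b": b, "rho": rho, "p": p,
             "weight": 1.0 - abs(rho)}
        )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p", "weight"])


def annotate_nodes(
    gene_ids: list[str],
    records: pd.DataFrame,
    p_ceiling: float = 300.0,
) -> pd.DataFrame:
    """Node display attributes from a per-gene score table.

    ``neg_log10_p`` is -log10 of the differential-expression p-value, capped
    at ``p_ceiling`` (underflowing p = 0 hits the cap with a warning);
    ``fold_change`` is copied through.
    """
    missing = [g for g in gene_ids if g not in records.index]
    if missing:
        raise KeyError(f"no score record for gene(s): {missing}")
    p = records.loc[gene_ids, "p_value"].to_numpy(dtype=float)
    if np.any(p == 0):
        warnings.warn(
            "p-value underflow (p = 0): -log10 p capped at "
            f"{p_ceiling}", stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        neg_log10_p = np.minimum(-np.log10(p), p_ceiling)
    return pd.DataFrame(
        {
            "neg_log10_p": neg_log10_p,
            "fold_change": records.loc[gene_ids, "fold_change"].to_numpy(),
        },
        index=pd.Index(gene_ids, name="id"),
    )


def minimum_spanning_tree(edges: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Kruskal MST of a complete weighted graph given as an edge table.

    Ties in edge weight are broken by lexicographic node-pair order so the
    result is deterministic and independent of input row order.  Returns the
    edge table with an ``in_mst`` flag and an ``edge_width`` display column
    (-log10 of the Spearman p), plus the tree's total weight.
    """
    if len(edges) == 0:
        raise ValueError("need at least 2 nodes")
    nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    n_expected = len(nodes) * (len(nodes) - 1) // 2
    if len(edges) != n_expected:
        raise ValueError(
            f"expected complete graph with {n_expected} edges, got {len(edges)}"
        )
    g = nx.Graph()
    g.add_nodes_from(nodes)
    # stable Kruskal sort + lexicographic insertion order => deterministic ties
    canon = edges.assign(
        ka=edges[["node_a", "node_b"]].min(axis=1),
        kb=edges[["node_a", "node_b"]].max(axis=1),
    ).sort_values(["ka", "kb"], kind="stable")
    for a, b, w in zip(canon["ka"], canon["kb"], canon["weight"]):
        g.add_edge(a, b, weight=float(w))
    tree = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")
    tree_pairs = {_pair_key(a, b) for a, b in tree.edges}

    out = edges.copy()
    out["in_mst"] = [
        _pair_key(a, b) in tree_pairs
        for a, b in zip(out["node_a"], out["node_b"])
    ]
    with np.errstate(divide="ignore"):
        out["edge_width"] = -np.log10(out["p"].to_numpy(dtype=float))
    total = float(out.loc[out["in_mst"], "weight"].sum())
    return out, total


def correlation_mst(
    dataset: ExpressionDataset,
    gene_ids: list[str],
    records: pd.DataFrame,
    sample_labels: list[str] | None = None,
    p_ceiling: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """One-call pipeline: edges -> MST -> node annotations.

    Returns (edge table with in_mst flags, node table, tree total weight).
    """
    edges = spearman_edges(dataset, gene_ids, sample_labels=sample_labels)
    edges, total = minimum_spanning_tree(edges)
    nodes = annotate_nodes(sorted(gene_ids), records, p_ceiling=p_ceiling)
    return edges, nodes, total
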