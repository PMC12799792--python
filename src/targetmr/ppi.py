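"""Protein-protein interaction aggregation and neighborhood features.

Multiple PPI resources are merged into one undirected network.  Scored
resources are filtered to their empirical 0.8 score quantile (keeping the top
20% of interactions); unscored resources contribute wholesale.  Per-resource
provenance is kept on each edge.  Neighborhood features summarize whether a
gene's first-degree partners carry genetic or drug support for the same
trait.
"""

from __future__ import annotations

from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_network", "neighborhood_features"]

SCORE_QUANTILE = 0.8


def build_network(
    edge_lists: Mapping[str, pd.DataFrame],
    score_quantile: float = SCORE_QUANTILE,
) -> nx.Graph:
    """Union PPI graph over per-resource edge lists.

    Each frame needs (gene_a, gene_b) and optionally a ``score`` column; a
    resource is treated as scored when any score is present.  Scored
    resources keep edges with score >= their empirical ``score_quantile``
    (linear-interpolation quantile).  Self-loops are dropped and duplicate
    unordered pairs collapse; each retained edge records the contributing
    resources in its ``resources`` set attribute.
    """
    graph = nx.Graph()
    for resource, df in edge_lists.items():
        df = df.dropna(subset=["gene_a", "gene_b"])
        df = df[df["gene_a"] != df["gene_b"]]
        scored = "score" in df.columns and df["score"].notna().any()
        if scored:
            cutoff = float(np.quantile(df["score"].dropna(), score_quantile))
            df = df[df["score"] >= cutoff]
        seen = set()
        for row in df.itertuples(index=False):
            a, b = sorted((row.gene_a, row.gene_b))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            if graph.has_edge(a, b):
                graph[a][b]["resources"].add(resource)
            else:
                graph.add_edge(a, b, resources={resource})
    return graph


def neighborhood_features(
    gene: str,
    trait: str,
    network: nx.Graph,
    selected_pairs: set[tuple[str, str]],
    approved_for_trait: Callable[[str, str], bool] | None = None,
) -> dict:
    """First-degree neighborhood features of one gene-trait pair.

    Returns the gene's degree in the union graph, the number of distinct
    neighbors with a selected MR result for the same trait, a flag for any
    neighbor being an approved drug target for a matching trait, and
    per-resource presence indicators.  A gene absent from the network gets
    zeros.
    """
    if gene not in network:
        return {
            "degree": 0,
            "n_neighbors_sig_same_trait": 0,
            "any_neighbor_approved_same_trait": False,
            "resources": frozenset(),
        }
    neighbors = list(network.neighbors(gene))
    n_sig = sum(1 for nb in neighbors if (nb, trait) in selected_pairs)
    any_approved = False
    if approved_for_trait is not None:
        any_approved = any(approved_for_trait(nb, trait) for nb in neighbors)
    resources = frozenset().union(
        *(network[gene][nb]["resources"] for nb in neighbors)
    ) if neighbors else frozenset()
    return {
        "degree": len(neighbors),
        "n_neighbors_sig_same_trait": int(n_sig),
        "any_neighbor_approved_same_trait": bool(any_approved),
        "resources": resources,
    }
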