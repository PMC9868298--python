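"""Genus co-occurrence networks with Walktrap community detection.

Edges connect genera whose relative abundances are strongly rank-correlated
across samples (Spearman rho above a threshold, Bonferroni-significant).
Communities are found with the Pons-Latapy random-walk (Walktrap)
agglomeration, cut at maximum modularity.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Only pairwise-complete observations are used; fewer than 4 complete
    pairs leaves the correlation undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 4:
        logger.warning(
            "fewer than 4 complete pairs; Spearman correlation undefined"
        )
        return float("nan"), float("nan")
    res = sps.spearmanr(x[mask], y[mask])
    return float(res.statistic), float(res.pvalue)


def build_network(
    genus_table: pd.DataFrame,
    min_abund: float = 0.0005,
    rho_min: float = 0.8,
    alpha: float = 0.05,
    use_abs: bool = False,
) -> nx.Graph:
    """Correlation-filtered genus co-occurrence graph.

    ``genus_table`` holds relative abundances (fractions) of genera (rows)
    across the samples of one group (columns).  Genera whose mean relative
    abundance exceeds ``min_abund`` are kept as candidate nodes; an edge is
    drawn when rho > ``rho_min`` (|rho| with ``use_abs``) and the raw
    p-value stays below ``alpha`` after Bonferroni multiplication by the
    number of genus pairs tested.  Only nodes with at least the abundance
    filter survive; the graph is simple and undirected.
    """
    if genus_table.shape[1] < 4:
        raise ValueError("need at least 4 samples to build a network")
    mean_abund = genus_table.mean(axis=1, skipna=True)
    kept = mean_abund[mean_abund > min_abund].index.tolist()
    graph = nx.Graph()
    if len(kept) < 2:
        logger.warning(
            "fewer than 2 genera pass the abundance filter; empty network"
        )
        for g in kept:
            graph.add_node(g, mean_abund=float(mean_abund[g]))
        return graph
    for g in kept:
        graph.add_node(g, mean_abund=float(mean_abund[g]))
    pairs = list(itertools.combinations(kept, 2))
    n_tests = len(pairs)
    for a, b in pairs:
        rho, p = spearman_rho(genus_table.loc[a], genus_table.loc[b])
        if math.isnan(rho):
            continue
        strength = abs(rho) if use_abs else rho
        adj_p = min(p * n_tests, 1.0)
        if strength > rho_min and adj_p < alpha:
            graph.add_edge(
                a, b, rho=rho, p=p, adj_p=adj_p, sign=1 if rho >= 0 else -1
            )
    graph.graph["n_tests"] = n_tests
    return graph


def walktrap_communities(graph: nx.Graph, steps: int = 4) -> dict[str, int]:
    """Walktrap community partition cut at maximum modularity.

    Deterministic for a fixed graph; disconnected components are never
    merged (merging disconnected communities cannot raise modularity).
    Isolated nodes form singleton communities.
    """
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    g = ig.Graph()
    g.add_vertices(len(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    g.add_edges([(index[u], index[v]) for u, v in graph.edges])
    dendrogram = g.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()
    return {n: clustering.membership[index[n]] for n in nodes}


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    largest_module_size: int
    largest_module_members: tuple[str, ...]


def network_summary(
    graph: nx.Graph, partition: dict[str, int] | None = None
) -> NetworkSummary:
    """Node/edge counts, mean degree 2E/N (one decimal) and largest module."""
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    avg = round(2 * e / n, 1) if n else 0.0
    if partition is None:
        partition = walktrap_communities(graph) if n else {}
    members: tuple[str, ...] = ()
    if partition:
        by_comm: dict[int, list[str]] = {}
        for node, comm in partition.items():
            by_comm.setdefault(comm, []).append(node)
        largest = max(by_comm.values(), key=lambda m: (len(m), sorted(m)))
        members = tuple(sorted(largest))
    return NetworkSummary(n, e, avg, len(members), members)


# -- graph IO -----------------------------------------------------------------


def write_network(
    graph: nx.Graph,
    edge_path: str | Path,
    node_path: str | Path,
    partition: dict[str, int] | None = None,
    names: dict[str, str] | None = None,
) -> None:
    """Edge-list and node TSVs; GraphML export is available via networkx."""
    names = names or {}
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\trho\tp\tadj_p\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data['rho']!r}\t{data['p']!r}\t{data['adj_p']!r}\n"
            )
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tname\tmean_abund\tcommunity\n")
        partition = partition or {}
        for node in sorted(graph.nodes):
            fh.write(
                f"{node}\t{names.get(node, node)}\t"
                f"{graph.nodes[node].get('mean_abund', float('nan'))!r}\t"
                f"{partition.get(node, '')}\n"
            )
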