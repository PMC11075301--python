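"""Pathway correlation networks and MCODE-style core-cluster extraction.

The clustering follows the Bader-Hogue MCODE algorithm: vertices are
weighted by the density of the highest k-core of their closed
neighbourhood times that core's k; clusters grow greedily from the
highest-weight unvisited seed, admitting neighbours whose weight is
within ``node_score_cutoff`` of the seed's, then are haircut (singly
connected members removed) and filtered for containing at least a
``k_core``-core. Cluster score = density x size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class CoreCluster:
    members: list
    score: float
    density: float
    rank: int = 0


def build_pathway_network(
    pathway_table, r_cut: float = 0.8, p_cut: float = 0.05
) -> nx.Graph:
    """All-pairs Pearson network over pathway abundance profiles.

    Edges keep pairs with |r| >= r_cut and two-sided p < p_cut.
    Constant pathways are excluded with a warning.
    """
    values = np.asarray(pathway_table, dtype=float)
    ids = [str(i) for i in getattr(pathway_table, "index", range(values.shape[0]))]
    if values.shape[0] < 2:
        raise AnalysisError("need at least two pathways")
    if values.shape[1] < 4:
        raise AnalysisError("need at least four samples")
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        for i in np.flatnonzero(constant):
            logger.warning("excluding constant pathway %s", ids[i])
        values = values[~constant]
        ids = [x for x, c in zip(ids, constant) if not c]
    if values.shape[0] < 2:
        g = nx.Graph(r_cut=float(r_cut), p_cut=float(p_cut))
        g.add_nodes_from(ids)
        return g
    n_samples = values.shape[1]
    corr = np.clip(np.corrcoef(values), -1.0, 1.0)
    # two-sided p from the t transform of r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = corr * np.sqrt((n_samples - 2) / (1 - corr**2))
    p = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    p[np.abs(corr) >= 1.0] = 0.0
    g = nx.Graph(r_cut=float(r_cut), p_cut=float(p_cut))
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = (np.abs(corr[iu, ju]) >= r_cut) & (p[iu, ju] < p_cut)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], weight=float(corr[i, j]), p=float(p[i, j]))
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    if g.number_of_edges() == 0:
        return 0, g
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values())
    core = g.subgraph([v for v, c in core_numbers.items() if c >= k])
    return k, core


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict:
    weights = {}
    for v in g.nodes():
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        k, core = _highest_k_core(closed)
        weights[v] = k * _density(core)
    return weights


def mcode_clusters(
    net: nx.Graph,
    degree_cutoff: int = 2,
    k_core: int = 2,
    node_score_cutoff: float = 0.2,
    max_depth: int = 100,
    haircut: bool = True,
) -> list[CoreCluster]:
    """Ranked vertex-disjoint dense clusters of a network."""
    if net.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(net, degree_cutoff)
    visited: set = set()
    clusters: list[CoreCluster] = []
    seeds = sorted(net.nodes(), key=lambda v: (-weights[v], str(v)))
    for seed in seeds:
        if seed in visited or net.degree(seed) < degree_cutoff:
            continue
        if weights[seed] <= 0:
            continue
        admit = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for nb in net.neighbors(v):
                    if nb in members or nb in visited:
                        continue
                    if weights[nb] >= admit:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        visited |= members
        sub = net.subgraph(members)
        if haircut:
            kept = [v for v in sub.nodes() if sub.degree(v) >= 2]
            sub = net.subgraph(kept)
        if sub.number_of_nodes() == 0:
            continue
        core_numbers = nx.core_number(sub) if sub.number_of_edges() else {}
        if not core_numbers or max(core_numbers.values()) < k_core:
            continue
        density = _density(sub)
        clusters.append(
            CoreCluster(sorted(sub.nodes(), key=str), density * sub.number_of_nodes(),
                        density)
        )
    clusters.sort(key=lambda c: (-c.score, c.members))
    for i, c in enumerate(clusters):
        c.rank = i + 1
    return clusters


def cluster_overlap(
    clusters_x: list[CoreCluster],
    clusters_y: list[CoreCluster],
    top_n: int = 3,
) -> np.ndarray:
    """|members_i intersect members_j| for the top_n clusters of each side."""
    cx = clusters_x[:top_n]
    cy = clusters_y[:top_n]
    out = np.zeros((len(cx), len(cy)), dtype=int)
    for i, a in enumerate(cx):
        sa = set(a.members)
        for j, b in enumerate(cy):
            out[i, j] = len(sa & set(b.members))
    return out
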