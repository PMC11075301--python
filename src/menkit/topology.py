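"""Structural index panel, scale-free fit and degree-preserving nulls.

All structural indices are computed on the unsigned, unweighted skeleton
of the network; edge signs only enter the positive/negative link counts.
Geodesic distance (GD) is averaged over reachable unordered pairs so it
stays finite on multi-component networks; connectedness (Con) is the
fraction of unordered pairs that are reachable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import AnalysisError
from .modules import detect_modules

logger = logging.getLogger(__name__)


def _geodesic_and_connectedness(g: nx.Graph) -> tuple[float, float]:
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    if total_pairs == 0:
        return float("nan"), float("nan")
    path_sum = 0.0
    reachable = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        reachable += m * (m - 1) // 2
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
    gd = path_sum / (2 * reachable) if reachable else float("nan")
    return gd, reachable / total_pairs


def topology_indices(men: nx.Graph) -> dict:
    """Structural subset of the per-network index panel.

    Returns nodes, links, avg_degree, avg_clustering, geodesic,
    connectedness, positive/negative link counts and the P/N ratio
    (None when there are no negative links).
    """
    n = men.number_of_nodes()
    if n == 0:
        raise AnalysisError("network is empty")
    m = men.number_of_edges()
    signs = [d.get("sign", 1 if d.get("weight", 1) > 0 else -1)
             for _, _, d in men.edges(data=True)]
    positive = sum(1 for s in signs if s > 0)
    negative = m - positive
    gd, con = _geodesic_and_connectedness(men)
    return {
        "nodes": n,
        "links": m,
        "avg_degree": 2 * m / n,
        "avg_clustering": nx.average_clustering(men) if n else float("nan"),
        "geodesic": gd,
        "connectedness": con,
        "positive_links": positive,
        "negative_links": negative,
        "pn_ratio": positive / negative if negative else None,
    }


def scale_free_fit(men: nx.Graph) -> tuple[float, float] | None:
    """OLS of log10 P(k) on log10 k over the observed degree histogram.

    Returns (slope, r_squared), or None (with a warning) when fewer
    than three distinct positive degrees are observed.
    """
    degrees = np.array([d for _, d in men.degree()])
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        warnings.warn("fewer than three distinct degrees; scale-free fit undefined",
                      stacklevel=2)
        return None
    pk = counts / degrees.size
    fit = stats.linregress(np.log10(ks), np.log10(pk))
    return float(fit.slope), float(fit.rvalue**2)


@dataclass
class NullEnsemble:
    n_random: int
    means: dict
    sds: dict
    z_scores: dict
    modularities: list[float]


def null_ensemble(
    men: nx.Graph,
    n_random: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int | None = None,
) -> NullEnsemble:
    """Maslov-Sneppen degree-preserving rewired ensemble.

    Each null graph is produced by double-edge swaps on the unweighted
    skeleton (degree sequence preserved exactly). Per-null average
    clustering, geodesic distance and greedy modularity are summarized
    as mean, sd and z = (empirical - mean) / sd.
    """
    m = men.number_of_edges()
    if m < 2:
        raise AnalysisError("need at least two edges to rewire")
    rng = np.random.default_rng(seed)
    emp = {
        "avg_clustering": nx.average_clustering(men),
        "geodesic": _geodesic_and_connectedness(men)[0],
        "modularity": detect_modules(men).modularity,
    }
    samples: dict[str, list[float]] = {k: [] for k in emp}
    for _ in range(n_random):
        null = nx.Graph(men.edges())
        nswap = n_swaps_per_edge * m
        try:
            nx.double_edge_swap(
                null, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError as exc:
            raise AnalysisError(f"graph too small to rewire: {exc}") from exc
        except nx.NetworkXAlgorithmError:
            logger.debug("swap budget exhausted; using partial rewiring")
        samples["avg_clustering"].append(nx.average_clustering(null))
        samples["geodesic"].append(_geodesic_and_connectedness(null)[0])
        samples["modularity"].append(detect_modules(null).modularity)
    means = {k: float(np.mean(v)) for k, v in samples.items()}
    sds = {k: float(np.std(v, ddof=1)) for k, v in samples.items()}
    z = {
        k: (emp[k] - means[k]) / sds[k] if sds[k] > 0 else float("nan")
        for k in emp
    }
    return NullEnsemble(n_random, means, sds, z, samples["modularity"])
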