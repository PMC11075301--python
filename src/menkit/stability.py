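"""Network stability: global efficiency, vulnerability, and robustness
under random or targeted (module-hub) node removal.

Robustness counts survivors that keep at least one link after removal;
an isolated survivor is treated as lost from the network (configurable
via ``prune``). Vulnerability is the largest relative drop in global
efficiency over all single-node deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import AnalysisError


@dataclass
class RobustnessResult:
    mode: str
    mean: float
    sd: float
    values: list[float]
    n_reps: int
    seed: int | None


def global_efficiency(men: nx.Graph) -> float:
    """E = mean over ordered pairs of 1 / d(i, j), with 1/inf = 0."""
    n = men.number_of_nodes()
    if n < 2:
        raise AnalysisError("global efficiency needs at least two nodes")
    inv_sum = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(men):
        inv_sum += sum(1.0 / d for d in dists.values() if d > 0)
    return inv_sum / (n * (n - 1))


def vulnerability(men: nx.Graph) -> float | None:
    """Max over nodes of (E - E_without_node) / E; None when E = 0."""
    if men.number_of_nodes() < 3:
        raise AnalysisError("vulnerability needs at least three nodes")
    e = global_efficiency(men)
    if e == 0:
        return None
    worst = -math.inf
    for node in men.nodes():
        rest = men.subgraph(n for n in men.nodes() if n != node)
        e_i = global_efficiency(rest) if rest.number_of_nodes() >= 2 else 0.0
        worst = max(worst, (e - e_i) / e)
    return worst


def _surviving_fraction(men: nx.Graph, removed: set, prune: bool) -> float:
    n = men.number_of_nodes()
    survivors = [v for v in men.nodes() if v not in removed]
    if prune:
        sub = men.subgraph(survivors)
        survivors = [v for v in survivors if sub.degree(v) > 0]
    return len(survivors) / n


def robustness(
    men: nx.Graph,
    mode: str = "random",
    fraction: float = 0.5,
    module_hubs=None,
    n_reps: int = 100,
    seed: int | None = None,
    prune: bool = True,
) -> RobustnessResult:
    """Fraction of species remaining after node removal plus pruning.

    mode 'random': remove ceil(fraction * n) uniformly chosen nodes,
    averaged over ``n_reps`` draws. mode 'targeted': remove every node
    in ``module_hubs`` once (deterministic). Survivors left without any
    link are pruned unless ``prune`` is disabled.
    """
    n = men.number_of_nodes()
    if n == 0:
        raise AnalysisError("network is empty")
    if mode == "random":
        if not 0 < fraction < 1:
            raise AnalysisError("fraction must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        n_remove = math.ceil(fraction * n)
        nodes = list(men.nodes())
        values = []
        for _ in range(n_reps):
            removed = set(
                rng.choice(len(nodes), size=n_remove, replace=False).tolist()
            )
            removed_nodes = {nodes[i] for i in removed}
            values.append(_surviving_fraction(men, removed_nodes, prune))
        arr = np.array(values)
        sd = float(arr.std(ddof=1)) if n_reps > 1 else 0.0
        return RobustnessResult("random", float(arr.mean()), sd, values, n_reps, seed)
    if mode == "targeted":
        hubs = set(module_hubs or [])
        value = _surviving_fraction(men, hubs, prune)
        return RobustnessResult("targeted", value, 0.0, [value], 1, seed)
    raise AnalysisError(f"unknown robustness mode {mode!r}")
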