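"""Module detection, (relative) modularity, and Zi-Pi role classification.

Modules are found by greedy (CNM) modularity maximization on the
unsigned, unweighted skeleton; the algorithm is deterministic for a
given graph, so the ``seed`` parameter exists only for interface
stability. Node roles follow the within-module degree z-score (Zi) and
participation coefficient (Pi) plane: module hubs (Zi high), connectors
(Pi high), network hubs (both); all three classes count as keystones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnalysisError

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"
KEYSTONE_ROLES = frozenset({ROLE_CONNECTOR, ROLE_MODULE_HUB, ROLE_NETWORK_HUB})


@dataclass
class ModulePartition:
    membership: dict  # node -> module id (0-based, largest module first)
    modularity: float

    @property
    def module_sizes(self) -> dict:
        sizes: dict[int, int] = {}
        for mod in self.membership.values():
            sizes[mod] = sizes.get(mod, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


def detect_modules(men: nx.Graph, seed: int | None = None) -> ModulePartition:
    """Greedy modularity communities on the unweighted skeleton.

    Module ids are assigned largest-first (ties broken by smallest
    member), so the labelling is deterministic.
    """
    if men.number_of_nodes() == 0:
        raise AnalysisError("network is empty")
    skeleton = nx.Graph(men.edges())
    skeleton.add_nodes_from(men.nodes())
    if skeleton.number_of_edges() == 0:
        communities = [{n} for n in skeleton.nodes()]
    else:
        communities = [
            set(c) for c in nx.community.greedy_modularity_communities(skeleton)
        ]
    communities.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(skeleton, communities)
    return ModulePartition(membership, float(q))


def relative_modularity(modularity: float, null_modularities) -> float | None:
    """RM = (M - mean(M_null)) / mean(M_null); None when the mean is 0."""
    null_mean = float(np.mean(list(null_modularities)))
    if null_mean == 0:
        return None
    return (modularity - null_mean) / null_mean


def module_size_summary(partition: ModulePartition, large_min: int = 5) -> dict:
    """Counts of small (< large_min nodes) and large (>= large_min) modules."""
    sizes = list(partition.module_sizes.values())
    large = [s for s in sizes if s >= large_min]
    return {
        "n_modules": len(sizes),
        "n_small_modules": len(sizes) - len(large),
        "n_large_modules": len(large),
        "nodes_in_large_modules": sum(large),
    }


def zi_pi_roles(
    men: nx.Graph,
    partition: ModulePartition,
    zi_cut: float = 2.5,
    pi_cut: float = 0.62,
) -> pd.DataFrame:
    """Per-node Zi, Pi and topological role.

    Zi is the z-score of the within-module degree relative to the node's
    module (Zi = 0 when the module's within-degree sd is 0); Pi is
    1 - sum_s (k_is / k_i)^2 over modules s. Cutoffs default to the
    Guimera-Amaral convention (2.5 / 0.62).
    """
    membership = partition.membership
    for node in men.nodes():
        if node not in membership:
            raise AnalysisError(f"partition does not cover node {node!r}")
        if men.degree(node) == 0:
            raise AnalysisError(f"isolated node {node!r} in network")
    # within-module degree per node
    within: dict = {}
    per_module_counts: dict = {}
    for node in men.nodes():
        counts: dict[int, int] = {}
        for nb in men.neighbors(node):
            mod = membership[nb]
            counts[mod] = counts.get(mod, 0) + 1
        per_module_counts[node] = counts
        within[node] = counts.get(membership[node], 0)
    # module-level mean/sd of within-degree
    module_members: dict[int, list] = {}
    for node in men.nodes():
        module_members.setdefault(membership[node], []).append(node)
    mod_stats = {}
    for mod, members in module_members.items():
        vals = np.array([within[n] for n in members], dtype=float)
        mod_stats[mod] = (vals.mean(), vals.std())
    rows = []
    for node in men.nodes():
        k = men.degree(node)
        mean_w, sd_w = mod_stats[membership[node]]
        zi = (within[node] - mean_w) / sd_w if sd_w > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[node].values())
        if zi > zi_cut and pi > pi_cut:
            role = ROLE_NETWORK_HUB
        elif zi > zi_cut:
            role = ROLE_MODULE_HUB
        elif pi > pi_cut:
            role = ROLE_CONNECTOR
        else:
            role = ROLE_PERIPHERAL
        rows.append((node, membership[node], k, zi, pi, role))
    frame = pd.DataFrame(
        rows, columns=["node", "module", "degree", "zi", "pi", "role"]
    ).set_index("node")
    return frame


def keystones(roles: pd.DataFrame) -> list:
    """Nodes classified as connector, module hub or network hub."""
    return list(roles.index[roles["role"].isin(KEYSTONE_ROLES)])
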