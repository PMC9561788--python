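"""Degree-preserving random networks for topology significance.

The null model is Maslov–Sneppen rewiring: repeated double-edge swaps
(a,b),(c,d) -> (a,d),(c,b) that preserve every node's degree exactly while
randomizing the wiring.  An ensemble of rewired replicas yields the
mean +/- sd of each topology metric under the null, and a z-score for the
empirical value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .topology import PMEN, avg_clustering, avg_path_length, greedy_modules

logger = logging.getLogger(__name__)

NULL_METRICS = ("avg_path_length", "avg_clustering", "modularity")


def rewire(net: PMEN, swaps_per_edge: int = 100, seed: int | None = None) -> PMEN:
    """One Maslov–Sneppen randomization of the network.

    Performs about `swaps_per_edge` * n_edges successful double-edge swaps,
    rejecting any swap that would create a self-loop or duplicate edge.
    Edge signs (with their correlation weights) are then redistributed at
    random over the new edge set, preserving the global positive-link
    count but breaking any sign-topology association.  Graphs admitting no
    valid swap (e.g. a triangle) are returned unchanged with a warning.
    Deterministic for a given seed.
    """
    if net.n_links < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    g.add_edges_from(net.graph.edges)
    nswap = swaps_per_edge * net.n_links
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(2**31)))
    except nx.NetworkXException as exc:
        # fewer than four nodes, or swap attempts exhausted; degrees are
        # preserved either way
        logger.warning("rewire: %s; returning graph as-is", exc)
    # reassign the weight/sign multiset onto the rewired edge set
    payload = [
        (d["weight"], d["sign"]) for _, _, d in net.graph.edges(data=True)
    ]
    order = rng.permutation(len(payload))
    for (u, v), k in zip(g.edges, order):
        w, s = payload[k]
        g.edges[u, v].update(weight=w, sign=s)
    rewired = PMEN(graph=g, threshold=net.threshold,
                   label=f"{net.label}:rewired" if net.label else "rewired")
    assert sorted(d for _, d in g.degree) == sorted(
        d for _, d in net.graph.degree
    ), "degree sequence not preserved"
    return rewired


@dataclass
class NullEnsembleSummary:
    """Ensemble mean +/- sd of topology metrics and the empirical z-scores."""

    label: str
    n_random: int
    empirical: dict
    mean: dict
    sd: dict
    z: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_random": self.n_random,
            "empirical": self.empirical,
            "random_mean": self.mean,
            "random_sd": self.sd,
            "z_score": self.z,
        }


def null_summary(net: PMEN, n_random: int = 100, swaps_per_edge: int = 100,
                 seed: int | None = None,
                 modules: dict | None = None,
                 modularity: float | None = None) -> NullEnsembleSummary:
    """Topology of `n_random` degree-preserving randomizations of `net`.

    For each replica the average path length, average clustering and
    greedy modularity are computed; the summary reports their ensemble
    mean and standard deviation plus z = (empirical - mean)/sd.  With a
    single replica the sd (hence z) is undefined and reported as None.
    """
    if modules is None or modularity is None:
        modules, modularity = greedy_modules(net)
    empirical = {
        "avg_path_length": avg_path_length(net),
        "avg_clustering": avg_clustering(net),
        "modularity": modularity,
    }
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_random)]
    samples = {m: [] for m in NULL_METRICS}
    for s in child_seeds:
        r = rewire(net, swaps_per_edge=swaps_per_edge, seed=s)
        _, m_r = greedy_modules(r)
        samples["avg_path_length"].append(avg_path_length(r))
        samples["avg_clustering"].append(avg_clustering(r))
        samples["modularity"].append(m_r)
    mean = {m: float(np.mean(v)) for m, v in samples.items()}
    if n_random < 2:
        logger.warning("null_summary: n_random < 2, sd and z undefined")
        sd = {m: None for m in NULL_METRICS}
        z = {m: None for m in NULL_METRICS}
    else:
        sd = {m: float(np.std(v, ddof=1)) for m, v in samples.items()}
        z = {}
        for m in NULL_METRICS:
            if sd[m] == 0:
                logger.warning("null_summary: zero sd for %s, z undefined", m)
                z[m] = None
            else:
                z[m] = float((empirical[m] - mean[m]) / sd[m])
    return NullEnsembleSummary(label=net.label, n_random=n_random,
                               empirical=empirical, mean=mean, sd=sd, z=z)
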