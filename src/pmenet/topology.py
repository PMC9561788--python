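"""Signed co-occurrence network construction and topology metrics.

A pMEN (phylogenetic molecular ecological network) is an undirected graph
whose nodes are ASVs and whose edges are correlations surviving the
similarity threshold.  Edges keep the correlation value and its sign as
attributes; all topology metrics (path length, clustering, modularity)
are computed on the unsigned, unweighted skeleton, which is how single
summary values are reported for networks with mixed-sign links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

from .abundance import RANKS
from .correlation import CorrelationMatrix

logger = logging.getLogger(__name__)


@dataclass
class PMEN:
    """A signed co-occurrence network at a fixed similarity threshold.

    `graph` is an undirected networkx graph; node attributes include the
    taxonomy lineage (one attribute per rank) and, once computed, module
    id, Zi, Pi and role; edge attributes are `weight` (the correlation)
    and `sign` ('+' or '-').  Isolated ASVs are never part of the network.
    """

    graph: nx.Graph
    threshold: float
    label: str = ""

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("network must not contain self-loops")
        for u, v, d in g.edges(data=True):
            w = d.get("weight")
            if w is None or abs(w) + 1e-12 < self.threshold:
                raise ValueError(
                    f"edge ({u},{v}) violates |weight| >= threshold"
                )
            if d.get("sign") not in ("+", "-") or (w > 0) != (d["sign"] == "+"):
                raise ValueError(f"edge ({u},{v}) sign/weight mismatch")
        isolated = [n for n, deg in g.degree if deg == 0]
        if isolated:
            raise ValueError(f"isolated nodes not allowed: {isolated[:5]}")

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def positive_link_proportion(self) -> float:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return sum(s == "+" for s in signs) / len(signs)

    def degree_sequence(self) -> list[int]:
        return sorted((d for _, d in self.graph.degree), reverse=True)

    # -- serialization ----------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        g.graph["threshold"] = self.threshold
        g.graph["label"] = self.label
        nx.write_graphml(g, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "PMEN":
        g = nx.read_graphml(str(path))
        threshold = float(g.graph.pop("threshold"))
        label = str(g.graph.pop("label", ""))
        return cls(graph=nx.Graph(g), threshold=threshold, label=label)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            row = {"node": n, "degree": self.graph.degree[n]}
            row.update(d)
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])

    def export_tables(self, outdir: str | Path, prefix: str = "") -> None:
        """Cytoscape-importable node and edge TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.node_table().to_csv(outdir / f"{prefix}nodes.tsv", sep="\t", index=False)
        self.edge_table().to_csv(outdir / f"{prefix}edges.tsv", sep="\t", index=False)


def build_network(corr: CorrelationMatrix, t: float,
                  taxonomy: pd.Series | None = None,
                  label: str = "") -> PMEN:
    """Build the signed network of correlations with |rho| >= t.

    Nodes are ASVs with at least one surviving link; each edge stores the
    correlation as `weight` and its sign.  Taxonomy lineages, if given,
    are attached as per-rank node attributes.
    """
    if not (0 < t < 1):
        raise ValueError("threshold must lie in (0, 1)")
    v = corr.values
    iu, ju = np.triu_indices(corr.size, k=1)
    keep = np.abs(v[iu, ju]) >= t
    if not keep.any():
        raise ValueError(f"empty network at threshold {t}")
    g = nx.Graph()
    for i, j in zip(iu[keep], ju[keep]):
        w = float(v[i, j])
        g.add_edge(corr.asv_ids[i], corr.asv_ids[j], weight=w,
                   sign="+" if w > 0 else "-")
    if taxonomy is not None:
        for n in g.nodes:
            if n in taxonomy.index:
                parts = [p.strip() for p in str(taxonomy.loc[n]).split(";")]
                parts += [""] * (len(RANKS) - len(parts))
                for rank, name in zip(RANKS, parts):
                    g.nodes[n][rank] = name
    return PMEN(graph=g, threshold=t, label=label)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def powerlaw_r2(degree_sequence) -> float | None:
    """R-squared of the log-log regression of degree frequency on degree.

    Fits log10(frequency of degree k) against log10(k) by least squares
    over degrees with nonzero frequency; a value near one indicates a
    scale-free degree distribution.  Undefined (None) with fewer than
    three distinct degree values.
    """
    degrees = np.asarray(list(degree_sequence), dtype=int)
    ks, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if len(ks) < 3:
        logger.warning("powerlaw_r2: fewer than 3 distinct degrees; undefined")
        return None
    res = stats.linregress(np.log10(ks), np.log10(freq))
    return float(res.rvalue ** 2)


def avg_path_length(net: PMEN) -> float:
    """Mean unweighted geodesic distance over connected ordered pairs.

    Pairs in different components are excluded, which keeps the value
    finite for fragmented networks; signs are ignored.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("average path length needs at least one edge")
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        n = len(comp)
        total += nx.average_shortest_path_length(sub) * n * (n - 1)
        pairs += n * (n - 1)
    return total / pairs


def avg_clustering(net: PMEN) -> float:
    """Mean local clustering coefficient (degree-1 nodes contribute 0)."""
    return nx.average_clustering(net.graph)


def modularity_of(graph: nx.Graph, partition: dict) -> float:
    """Newman modularity of a node -> module-id partition (direct formula)."""
    comms: dict = {}
    for n, c in partition.items():
        comms.setdefault(c, set()).add(n)
    return nx_community.modularity(graph, comms.values())


def greedy_modules(net: PMEN) -> tuple[dict, float]:
    """Agglomerative greedy modularity maximization (Clauset–Newman–Moore).

    Communities are merged pairwise while the modularity gain is positive,
    on the unsigned, unweighted skeleton.  Returns the node -> module-id
    assignment (ids ordered by each module's smallest node label, for
    determinism) and the Newman modularity M of the final partition.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("modularity needs at least one edge")
    if g.number_of_nodes() == 2:
        comms = [set(g.nodes)]
    else:
        comms = [set(c) for c in nx_community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: min(str(n) for n in c))
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    m = modularity_of(g, assignment)
    return assignment, float(m)


@dataclass
class TopologySummary:
    """The per-network metric vector reported for empirical networks."""

    label: str
    threshold: float
    network_size: int
    n_links: int
    powerlaw_r2: float | None
    avg_connectivity: float
    positive_link_proportion: float
    avg_path_length: float
    avg_clustering: float
    modularity: float
    n_modules: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.avg_connectivity - 2 * self.n_links / self.network_size) > 1e-9:
            raise ValueError("avg_connectivity must equal 2*links/size")
        if not (0 <= self.positive_link_proportion <= 1):
            raise ValueError("positive_link_proportion out of [0, 1]")
        if not (-0.5 - 1e-12 <= self.modularity <= 1 + 1e-12):
            raise ValueError("modularity out of [-0.5, 1]")

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "threshold": self.threshold,
            "network_size": self.network_size,
            "n_links": self.n_links,
            "powerlaw_r2": self.powerlaw_r2,
            "avg_connectivity": self.avg_connectivity,
            "positive_link_proportion": self.positive_link_proportion,
            "avg_path_length": self.avg_path_length,
            "avg_clustering": self.avg_clustering,
            "modularity": self.modularity,
            "n_modules": self.n_modules,
        }
        d.update(self.extras)
        return d


def topology_summary(net: PMEN,
                     modules: dict | None = None,
                     modularity: float | None = None) -> TopologySummary:
    """Assemble the full metric vector for one network.

    Modules are computed with `greedy_modules` unless a precomputed
    assignment (and its modularity) is supplied.
    """
    if modules is None or modularity is None:
        modules, modularity = greedy_modules(net)
    return TopologySummary(
        label=net.label,
        threshold=net.threshold,
        network_size=net.size,
        n_links=net.n_links,
        powerlaw_r2=powerlaw_r2(dict(net.graph.degree).values()),
        avg_connectivity=2 * net.n_links / net.size,
        positive_link_proportion=net.positive_link_proportion(),
        avg_path_length=avg_path_length(net),
        avg_clustering=avg_clustering(net),
        modularity=modularity,
        n_modules=len(set(modules.values())),
    )
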