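"""Between-network comparisons: shared nodes, metric deltas, subnetworks.

Networks built from different sample groups (treatments, layers, weeks)
share an ASV namespace, so their node sets can be intersected directly.
Comparisons here are descriptive: shared-node percentages, relative
percent changes of topology metrics, taxon-anchored first-neighbor
subnetworks, and a combined summary table laid out like the standard
empirical-vs-random topology tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .nulls import NullEnsembleSummary
from .topology import PMEN, TopologySummary

logger = logging.getLogger(__name__)


@dataclass
class SharedNodeReport:
    label_a: str
    label_b: str
    size_a: int
    size_b: int
    shared: int
    pct_of_union: float
    shared_nodes: list

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "size_a": self.size_a, "size_b": self.size_b,
            "shared": self.shared,
            "pct_of_union": round(self.pct_of_union, 1),
            "shared_nodes": self.shared_nodes,
        }


def shared_nodes(net_a: PMEN, net_b: PMEN) -> SharedNodeReport:
    """Node overlap of two networks, as a percentage of their node union.

    pct_of_union = 100 * shared / (size_a + size_b - shared).
    """
    a, b = set(net_a.graph.nodes), set(net_b.graph.nodes)
    inter = a & b
    if not inter:
        logger.warning("shared_nodes: %r and %r share no nodes",
                       net_a.label, net_b.label)
    union = len(a) + len(b) - len(inter)
    pct = 100.0 * len(inter) / union if union else 0.0
    return SharedNodeReport(
        label_a=net_a.label, label_b=net_b.label,
        size_a=len(a), size_b=len(b), shared=len(inter),
        pct_of_union=pct, shared_nodes=sorted(inter),
    )


def relative_percent_change(value_a: float, value_b: float) -> float | None:
    """100 * (a - b) / b; None (missing) when the reference b is zero."""
    if value_b == 0:
        logger.warning("relative_percent_change: zero reference value")
        return None
    return 100.0 * (value_a - value_b) / value_b


def _metric_value(summary, metric: str) -> float:
    if isinstance(summary, dict):
        return summary[metric]
    return getattr(summary, metric)


def metric_delta(summary_a, summary_b, metric: str) -> float | None:
    """Relative percent change of one metric between two topology summaries.

    Positive values mean network A exceeds network B.  Accepts
    TopologySummary objects or plain mappings.
    """
    return relative_percent_change(
        _metric_value(summary_a, metric), _metric_value(summary_b, metric)
    )


@dataclass
class SubnetworkView:
    """A taxon-anchored first-neighbor subnetwork.

    Anchors are the nodes whose lineage matches (rank, name); neighbors
    are nodes adjacent to at least one anchor.  The induced edge set keeps
    anchor-anchor and anchor-neighbor links only (neighbor-neighbor links
    are excluded so every reported link involves the anchor taxon).
    """

    rank: str
    name: str
    anchors: list
    neighbors: list
    edges: list  # (u, v, weight, sign)
    n_links: int
    positive_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "rank": self.rank, "name": self.name,
            "anchors": self.anchors, "neighbors": self.neighbors,
            "n_links": self.n_links,
            "positive_fraction": self.positive_fraction,
        }


def taxon_subnetwork(net: PMEN, rank: str, name: str) -> SubnetworkView:
    """Extract the subnetwork anchored on a taxon (case-insensitive match).

    Returns an empty view with a warning when the taxon has no node in the
    network (a taxon may simply be absent from a given group's network).
    """
    g = net.graph
    target = name.strip().lower()
    anchors = [n for n, d in g.nodes(data=True)
               if str(d.get(rank, "")).strip().lower() == target]
    if not anchors:
        logger.warning("taxon_subnetwork: no %s == %r in network %r",
                       rank, name, net.label)
        return SubnetworkView(rank=rank, name=name, anchors=[], neighbors=[],
                              edges=[], n_links=0, positive_fraction=None)
    anchor_set = set(anchors)
    edges = []
    neighbors: set = set()
    for a in anchors:
        for nb in g[a]:
            if nb in anchor_set and str(nb) < str(a):
                continue  # anchor-anchor edge already recorded
            d = g.edges[a, nb]
            edges.append((a, nb, d["weight"], d["sign"]))
            if nb not in anchor_set:
                neighbors.add(nb)
    pos = sum(1 for *_, s in edges if s == "+")
    return SubnetworkView(
        rank=rank, name=name, anchors=sorted(anchors),
        neighbors=sorted(neighbors), edges=edges, n_links=len(edges),
        positive_fraction=pos / len(edges) if edges else None,
    )


SUMMARY_COLUMNS = [
    "label", "threshold", "network_size", "powerlaw_r2", "avg_connectivity",
    "positive_links_pct", "avg_path_length", "avg_clustering", "modularity",
    "random_avg_path_length", "random_avg_clustering", "random_modularity",
]


def _fmt_pm(mean: float | None, sd: float | None) -> str:
    if mean is None:
        return ""
    if sd is None:
        return f"{mean:.3f}"
    return f"{mean:.3f} ± {sd:.3f}"


def summary_table(entries: list[tuple[TopologySummary, NullEnsembleSummary | None]]
                  ) -> pd.DataFrame:
    """One row per network: empirical metrics then random mean +/- sd.

    Percentages are shown to one decimal and unitless metrics to three,
    matching the conventional display precision of these tables.
    """
    rows = []
    for summ, null in entries:
        row = {
            "label": summ.label,
            "threshold": summ.threshold,
            "network_size": summ.network_size,
            "powerlaw_r2": None if summ.powerlaw_r2 is None
            else round(summ.powerlaw_r2, 3),
            "avg_connectivity": round(summ.avg_connectivity, 3),
            "positive_links_pct": round(100 * summ.positive_link_proportion, 1),
            "avg_path_length": round(summ.avg_path_length, 3),
            "avg_clustering": round(summ.avg_clustering, 3),
            "modularity": round(summ.modularity, 3),
        }
        for metric in ("avg_path_length", "avg_clustering", "modularity"):
            key = f"random_{metric}"
            if null is None:
                row[key] = ""
            else:
                row[key] = _fmt_pm(null.mean.get(metric), null.sd.get(metric))
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
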