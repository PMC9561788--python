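"""Shared fixtures: tiny hand-written tables and graph builders."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pmenet import AbundanceTable, PMEN


@pytest.fixture
def toy_table() -> AbundanceTable:
    """3 ASVs x 4 samples with simple taxonomy and a 2-group design."""
    counts = pd.DataFrame(
        {
            "S1": [10, 0, 5],
            "S2": [20, 1, 4],
            "S3": [30, 2, 3],
            "S4": [40, 3, 2],
        },
        index=["ASV_1", "ASV_2", "ASV_3"],
    )
    taxonomy = pd.Series(
        {
            "ASV_1": "Bacteria;P1;C1;O1;F1;G1",
            "ASV_2": "Bacteria;P1;C2;O2;F2;G2",
            "ASV_3": "Bacteria;P2;C3;O3;F3;G3",
        }
    )
    metadata = pd.DataFrame(
        {
            "group": ["aeration", "aeration", "control", "control"],
            "layer": ["top", "top", "top", "top"],
            "week": [1, 2, 1, 2],
            "replicate": [1, 1, 1, 1],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return AbundanceTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


@pytest.fixture
def toy_files(tmp_path, toy_table):
    """The toy table written out in the TSV dialect `read_abundance` expects."""
    counts = tmp_path / "counts.tsv"
    toy_table.counts.rename_axis("asv_id").to_csv(counts, sep="\t")
    tax = tmp_path / "taxonomy.tsv"
    toy_table.taxonomy.rename("lineage").rename_axis("asv_id").to_frame().to_csv(
        tax, sep="\t")
    meta = tmp_path / "metadata.tsv"
    toy_table.metadata.rename_axis("sample").to_csv(meta, sep="\t")
    return counts, tax, meta


def make_pmen(graph: nx.Graph, threshold: float = 0.5, label: str = "",
              weight: float = 0.9) -> PMEN:
    """Wrap a plain graph as a PMEN with uniform positive edges."""
    g = nx.Graph(graph)
    for u, v in g.edges:
        g.edges[u, v].setdefault("weight", weight)
        w = g.edges[u, v]["weight"]
        g.edges[u, v]["sign"] = "+" if w > 0 else "-"
    return PMEN(graph=g, threshold=threshold, label=label)


@pytest.fixture
def bridged_cliques() -> PMEN:
    """Two 4-cliques joined by a single bridge edge (13 edges total)."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(base + i, base + j)
    g.add_edge(0, 4)
    return make_pmen(g)


@pytest.fixture
def design_table() -> AbundanceTable:
    """A 180-sample 2x5x3x6 design with 2 ASVs of constant counts."""
    import itertools

    rows = []
    for i, (g, w, l, r) in enumerate(
        itertools.product(("aeration", "control"), (1, 2, 3, 4, 9),
                          ("top", "middle", "bottom"), range(1, 7))
    ):
        rows.append({"sample": f"S{i:03d}", "group": g, "layer": l,
                     "week": w, "replicate": r})
    metadata = pd.DataFrame(rows).set_index("sample")
    counts = pd.DataFrame(
        np.ones((2, len(metadata)), dtype=int),
        index=["ASV_1", "ASV_2"], columns=metadata.index,
    )
    taxonomy = pd.Series({"ASV_1": "Bacteria;P1", "ASV_2": "Bacteria;P2"})
    return AbundanceTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
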