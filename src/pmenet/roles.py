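"""Node roles from within- and among-module connectivity (the ZP plane).

Following the Guimera–Amaral framework, each node gets a within-module
degree z-score Zi and a participation coefficient Pi, and is classified
into one of four topological roles by the conventional cutoffs Zi = 2.5
and Pi = 0.62:

    peripheral   Zi <= 2.5, Pi <= 0.62   links mostly inside its module
    module hub   Zi >  2.5, Pi <= 0.62   heavily connected within its module
    connector    Zi <= 2.5, Pi >  0.62   links spread across modules
    network hub  Zi >  2.5, Pi >  0.62   both of the above

Non-peripheral nodes are the keystone set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import PMEN

Z_CUT_DEFAULT = 2.5
P_CUT_DEFAULT = 0.62

ROLE_NAMES = ("peripheral", "module_hub", "connector", "network_hub")


@dataclass(frozen=True)
class RoleRecord:
    node: str
    module: int
    degree: int
    zi: float
    pi: float
    role: str


def within_module_degree(net: PMEN, modules: dict) -> dict:
    """kappa_i: number of links node i has to nodes in its own module."""
    g = net.graph
    return {
        n: sum(1 for nb in g[n] if modules[nb] == modules[n]) for n in g.nodes
    }


def within_module_z(net: PMEN, modules: dict) -> dict:
    """Within-module degree z-score Zi.

    Zi = (kappa_i - mean_module kappa) / sd_module kappa with the
    *population* standard deviation over the node's module.  Modules whose
    members all have the same within-module degree (e.g. cliques) have
    zero sd; their members get Zi = 0.
    """
    kappa = within_module_degree(net, modules)
    by_module: dict = {}
    for n, c in modules.items():
        by_module.setdefault(c, []).append(n)
    zi = {}
    for c, members in by_module.items():
        k = np.array([kappa[n] for n in members], dtype=float)
        sd = k.std()  # population sd
        mean = k.mean()
        for n, ki in zip(members, k):
            zi[n] = 0.0 if sd == 0 else float((ki - mean) / sd)
    return zi


def participation_coefficient(net: PMEN, modules: dict) -> dict:
    """Pi = 1 - sum_t (k_it / k_i)^2 over modules t.

    k_it counts node i's links into module t and k_i is its total degree;
    Pi is 0 when every link stays inside one module and approaches 1 as
    links spread evenly over many modules.
    """
    g = net.graph
    pi = {}
    for n in g.nodes:
        k_i = g.degree[n]
        per_module: dict = {}
        for nb in g[n]:
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi[n] = float(1.0 - sum((k / k_i) ** 2 for k in per_module.values()))
    return pi


def classify_role(zi: float, pi: float, z_cut: float = Z_CUT_DEFAULT,
                  p_cut: float = P_CUT_DEFAULT) -> str:
    """Pure (Zi, Pi) -> role mapping; both cutoffs are boundary-inclusive
    on the peripheral side (Zi <= z_cut and Pi <= p_cut is peripheral)."""
    high_z = zi > z_cut
    high_p = pi > p_cut
    if high_z and high_p:
        return "network_hub"
    if high_z:
        return "module_hub"
    if high_p:
        return "connector"
    return "peripheral"


def classify_roles(net: PMEN, modules: dict, z_cut: float = Z_CUT_DEFAULT,
                   p_cut: float = P_CUT_DEFAULT) -> list[RoleRecord]:
    """Compute Zi, Pi and the role for every node; annotate the graph.

    Node attributes `module`, `Zi`, `Pi` and `role` are written onto the
    network in place, and the full record list is returned.
    """
    missing = [n for n in net.graph.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    zi = within_module_z(net, modules)
    pi = participation_coefficient(net, modules)
    records = []
    for n in net.graph.nodes:
        role = classify_role(zi[n], pi[n], z_cut, p_cut)
        rec = RoleRecord(node=n, module=int(modules[n]),
                         degree=int(net.graph.degree[n]),
                         zi=zi[n], pi=pi[n], role=role)
        net.graph.nodes[n].update(module=rec.module, Zi=rec.zi, Pi=rec.pi,
                                  role=rec.role)
        records.append(rec)
    return records


def role_table(records: list[RoleRecord]) -> pd.DataFrame:
    """ZP-plot export: one row per node with module, Zi, Pi and role."""
    return pd.DataFrame(
        [{"node": r.node, "module": r.module, "degree": r.degree,
          "Zi": r.zi, "Pi": r.pi, "role": r.role} for r in records]
    )


def keystone_census(records: list[RoleRecord]) -> dict:
    """Counts per role plus the keystone total (all non-peripherals)."""
    counts = {role: 0 for role in ROLE_NAMES}
    for r in records:
        counts[r.role] += 1
    counts["keystone"] = sum(counts[r] for r in ROLE_NAMES if r != "peripheral")
    return counts
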