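"""Pipeline orchestration: configuration, per-group runs, run manifests.

A run takes the three input tables, a list of sample-group selectors and
the preprocessing/threshold settings, and produces per group: the
preprocessed table, the threshold scan, the network (GraphML plus
Cytoscape-importable node/edge TSVs), the topology summary, the role
table and the null-ensemble summary — followed by cross-network reports
(shared nodes, metric deltas, a combined summary table).  Every run
writes a manifest echoing all resolved parameters and seeds, which alone
suffices to reproduce it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .abundance import (AbundanceTable, GroupSelector, filter_prevalence,
                        filter_relative_abundance, rarefy, read_abundance,
                        select_group, write_abundance)
from .compare import metric_delta, shared_nodes, summary_table
from .correlation import spearman_matrix
from .nulls import null_summary
from .rmt import scan_thresholds, select_threshold
from .roles import classify_roles, keystone_census, role_table
from .topology import build_network, greedy_modules, topology_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run (defaults = study settings)."""

    counts_path: str
    taxonomy_path: str
    metadata_path: str
    output_dir: str
    selectors: list = field(default_factory=list)  # list of GroupSelector
    rarefaction_depth: int = 48_000
    min_relative_abundance: float = 1e-5
    min_prevalence: float = 0.5
    threshold_mode: str = "fixed"  # "auto" | "fixed"
    fixed_threshold: float = 0.83
    scan_t_min: float = 0.01
    scan_t_max: float = 0.95
    scan_step: float = 0.01
    scan_alpha: float = 0.05
    n_random: int = 100
    swaps_per_edge: int = 100
    seed: int = 0
    write_correlation: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sels = [
            GroupSelector(where=s.get("where", {}), label=s.get("label", f"sel{i}"),
                          min_samples=s.get("min_samples", 9))
            for i, s in enumerate(raw.pop("selectors", []))
        ]
        return cls(selectors=sels, **raw)

    def resolved(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "selectors"}
        d["selectors"] = [
            {"label": s.label, "where": s.where, "min_samples": s.min_samples}
            for s in self.selectors
        ]
        return d


def _stage(label: str, stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed for selector {label!r}: {exc}"
        ) from exc
    logger.info("[%s] %s: %.2fs", label, stage, time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Returns a dict with, per selector label, the network, its summaries
    and output paths, plus the cross-network comparison reports.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_abundance(config.counts_path, config.taxonomy_path,
                           config.metadata_path)
    ss = np.random.SeedSequence(config.seed)
    selector_seeds = [int(s.generate_state(1)[0] % (2**31))
                      for s in ss.spawn(max(1, len(config.selectors)))]
    selectors = config.selectors or [GroupSelector(label="all")]

    results: dict = {"networks": {}, "comparisons": {}}
    entries = []
    for selector, sel_seed in zip(selectors, selector_seeds):
        label = selector.label
        sel_dir = outdir / label
        sel_dir.mkdir(parents=True, exist_ok=True)
        sub = _stage(label, "select_group", select_group, table, selector)
        sub = _stage(label, "rarefy", rarefy, sub, config.rarefaction_depth,
                     sel_seed)
        sub = _stage(label, "filter_relative_abundance",
                     filter_relative_abundance, sub,
                     config.min_relative_abundance)
        sub = _stage(label, "filter_prevalence", filter_prevalence, sub,
                     config.min_prevalence)
        write_abundance(sub, sel_dir, prefix="preprocessed_")
        corr = _stage(label, "spearman_matrix", spearman_matrix, sub)
        if config.write_correlation:
            np.savetxt(sel_dir / "correlation.tsv", corr.values,
                       delimiter="\t")
        scan = _stage(label, "scan_thresholds", scan_thresholds, corr,
                      config.scan_t_min, config.scan_t_max, config.scan_step,
                      config.scan_alpha)
        scan.to_tsv(sel_dir / "threshold_scan.tsv")
        t = _stage(label, "select_threshold", select_threshold, scan,
                   config.threshold_mode, config.fixed_threshold)
        net = _stage(label, "build_network", build_network, corr, t,
                     sub.taxonomy, label)
        modules, modularity = _stage(label, "greedy_modules", greedy_modules,
                                     net)
        records = _stage(label, "classify_roles", classify_roles, net, modules)
        summ = _stage(label, "topology_summary", topology_summary, net,
                      modules, modularity)
        null = _stage(label, "null_summary", null_summary, net,
                      config.n_random, config.swaps_per_edge, sel_seed,
                      modules, modularity)
        net.to_graphml(sel_dir / "network.graphml")
        net.export_tables(sel_dir)
        role_table(records).to_csv(sel_dir / "roles.tsv", sep="\t", index=False)
        (sel_dir / "topology_summary.json").write_text(
            json.dumps(summ.to_dict(), indent=2, default=float))
        (sel_dir / "null_summary.json").write_text(
            json.dumps(null.to_dict(), indent=2, default=float))
        (sel_dir / "keystone_census.json").write_text(
            json.dumps(keystone_census(records), indent=2))
        results["networks"][label] = {
            "network": net, "summary": summ, "null": null,
            "roles": records, "threshold": t, "dir": str(sel_dir),
        }
        entries.append((summ, null))

    labels = list(results["networks"])
    comparisons = {"shared_nodes": [], "metric_deltas": []}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = results["networks"][labels[i]]
            b = results["networks"][labels[j]]
            rep = shared_nodes(a["network"], b["network"])
            comparisons["shared_nodes"].append(rep.to_dict())
            for metric in ("positive_link_proportion", "avg_connectivity",
                           "avg_path_length", "avg_clustering", "modularity"):
                comparisons["metric_deltas"].append({
                    "label_a": labels[i], "label_b": labels[j],
                    "metric": metric,
                    "pct_change": metric_delta(a["summary"], b["summary"],
                                               metric),
                })
    table_df = summary_table(entries)
    table_df.to_csv(outdir / "summary_table.tsv", sep="\t", index=False)
    (outdir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=float))
    results["comparisons"] = comparisons
    results["summary_table"] = table_df

    manifest = {
        "config": config.resolved(),
        "selector_seeds": dict(zip(labels, selector_seeds)),
        "thresholds": {lb: results["networks"][lb]["threshold"]
                       for lb in labels},
        "n_samples_input": table.n_samples,
        "n_asvs_input": table.n_asvs,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float))
    results["manifest"] = manifest
    return results
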