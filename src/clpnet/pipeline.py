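"""Full-analysis orchestration: descriptives through stability, subgroup
networks, and all file exports.

``run_full_analysis`` executes the standard sequence — descriptives and
paired tests on the raw responses, nonparanormal transformation, node-wise
LASSO network estimation, edge thresholding, prediction centrality,
nonparametric bootstrap, case-dropping stability, and the clinical-cutoff
subgroup analysis — deterministically from one seed, and ``export_report``
writes every table plus a GraphML network and a JSON master report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import CentralityTable, centrality_report, compute_centrality
from .config import AnalysisConfig, config_to_dict
from .estimation import (CLPNResult, EdgeList, estimate_clpn, summarize_edges,
                         threshold_edges)
from .panel_io import PanelDataset
from .preprocess import (descriptive_table, descriptives_frame, paired_frame,
                         paired_table, transform_dataset)
from .stability import (BootstrapResult, StabilityResult, bootstrap_edges,
                        case_drop_stability)

__all__ = ["AnalysisReport", "SubgroupResult", "run_full_analysis",
           "subgroup_analysis", "export_report", "to_graphml"]


def _package_version() -> str:
    from clpnet import __version__
    return __version__


@dataclass
class SubgroupResult:
    """Per-group networks after splitting at the clinical cutoff."""

    cutoff: float
    n_high: int
    n_low: int
    high: CLPNResult
    low: CLPNResult
    high_edges: EdgeList
    low_edges: EdgeList
    warnings: list[str] = field(default_factory=list)

    def density_frame(self) -> pd.DataFrame:
        recs = []
        for name, res, edges, n in (("high", self.high, self.high_edges,
                                     self.n_high),
                                    ("low", self.low, self.low_edges,
                                     self.n_low)):
            off = res.crosslagged_weights()
            nz = off[off != 0.0]
            recs.append({
                "group": name, "n": n,
                "n_nonzero_crosslagged": int(nz.size),
                "mean_abs_crosslagged": float(np.mean(np.abs(nz)))
                if nz.size else 0.0,
                "threshold": edges.threshold,
                "n_edges_above_threshold": len(edges),
            })
        return pd.DataFrame(recs)


@dataclass
class AnalysisReport:
    """Everything one full run produces, plus provenance."""

    config: AnalysisConfig
    descriptives: pd.DataFrame
    paired_tests: pd.DataFrame
    network: CLPNResult
    edges: EdgeList
    edge_summary: dict
    centrality: CentralityTable
    centrality_ranking: dict
    bootstrap: BootstrapResult | None
    stability: StabilityResult | None
    subgroups: SubgroupResult | None
    skipped: list[str] = field(default_factory=list)

    def provenance(self) -> dict:
        cfg = config_to_dict(self.config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": cfg, "config_hash": cfg_hash,
                "seed": self.config.seed,
                "software": f"clpnet {_package_version()}"}

    def to_json(self) -> str:
        """Master JSON report; sufficient to regenerate every CSV."""
        payload: dict = {
            "provenance": self.provenance(),
            "skipped": self.skipped,
            "descriptives": self.descriptives.to_dict(orient="records"),
            "paired_tests": self.paired_tests.to_dict(orient="records"),
            "network": json.loads(self.network.to_json()),
            "edges": [e.__dict__ for e in self.edges.edges],
            "autoregressive_edges": [e.__dict__
                                     for e in self.edges.autoregressive],
            "edge_summary": {k: v for k, v in self.edge_summary.items()
                             if k != "top_edges"},
            "centrality": self.centrality.to_frame().to_dict(orient="records"),
        }
        if self.bootstrap is not None:
            payload["bootstrap"] = self.bootstrap.summary_frame().to_dict(
                orient="records")
        if self.stability is not None:
            payload["stability"] = {
                "cs": self.stability.cs,
                "curves": self.stability.curve_frame().to_dict(
                    orient="records"),
            }
        if self.subgroups is not None:
            payload["subgroups"] = self.subgroups.density_frame().to_dict(
                orient="records")
            payload["subgroup_warnings"] = self.subgroups.warnings
        return json.dumps(payload, sort_keys=True)


def run_full_analysis(dataset: PanelDataset, config: AnalysisConfig,
                      anxiety_construct: str = "GA") -> AnalysisReport:
    """Run the complete analysis sequence on a validated raw panel.

    Bootstrap / stability / subgroup stages with zero work configured
    (``n_boot=0`` etc.) are marked skipped rather than run empty.  Fully
    deterministic given ``config.seed``.
    """
    dataset.validate()
    skipped: list[str] = []

    desc = descriptives_frame(descriptive_table(dataset))
    paired = paired_frame(paired_table(dataset))

    transformed = transform_dataset(dataset)
    network = estimate_clpn(transformed, config)
    edges = threshold_edges(network, config.threshold_rule,
                            config.fixed_threshold)
    edge_summary = summarize_edges(edges)
    centrality = compute_centrality(transformed, network)
    ranking = centrality_report(centrality)

    if config.n_boot > 0:
        boot = bootstrap_edges(dataset, config, full_result=network)
    else:
        boot = None
        skipped.append("bootstrap")
    if config.n_drop_boot > 0:
        stab = case_drop_stability(dataset, config)
    else:
        stab = None
        skipped.append("stability")

    try:
        sub = subgroup_analysis(dataset, config,
                                anxiety_construct=anxiety_construct)
    except ValueError as exc:
        warnings.warn(f"subgroup analysis skipped: {exc}", RuntimeWarning)
        sub = None
        skipped.append("subgroups")

    return AnalysisReport(
        config=config, descriptives=desc, paired_tests=paired,
        network=network, edges=edges, edge_summary=edge_summary,
        centrality=centrality, centrality_ranking=ranking,
        bootstrap=boot, stability=stab, subgroups=sub, skipped=skipped)


def subgroup_analysis(dataset: PanelDataset, config: AnalysisConfig,
                      anxiety_construct: str = "GA") -> SubgroupResult:
    """Split at the clinical cutoff and estimate per-group networks.

    The cutoff applies to the anxiety construct's wave-1 sum score on the
    instrument's native 0-based scoring; when items are stored 1-based the
    offset is computed from the declared response ranges, never hard-coded.
    Groups: high = score >= cutoff, low = score < cutoff.  A group smaller
    than 10 x p triggers a stability caveat; an empty group is an error.
    """
    score = dataset.sum_score(anxiety_construct, wave=1, zero_based=True)
    high_mask = score >= config.subgroup_cutoff
    n_high = int(high_mask.sum())
    n_low = int((~high_mask).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"cutoff {config.subgroup_cutoff} produces an empty group "
            f"(high={n_high}, low={n_low})")
    caveats: list[str] = []
    p = dataset.n_nodes
    for name, n in (("high", n_high), ("low", n_low)):
        if n < 10 * p:
            msg = (f"{name}-anxiety group has n={n} < 10 x p={10 * p}; "
                   "subgroup network stability is limited")
            warnings.warn(msg, RuntimeWarning)
            caveats.append(msg)

    results = {}
    edge_lists = {}
    for name, mask in (("high", high_mask), ("low", ~high_mask)):
        sub = transform_dataset(dataset.subset(mask))
        res = estimate_clpn(sub, config)
        results[name] = res
        edge_lists[name] = threshold_edges(res, config.threshold_rule,
                                           config.fixed_threshold)
    return SubgroupResult(
        cutoff=config.subgroup_cutoff, n_high=n_high, n_low=n_low,
        high=results["high"], low=results["low"],
        high_edges=edge_lists["high"], low_edges=edge_lists["low"],
        warnings=caveats)


def to_graphml(result: CLPNResult, path, edges: EdgeList | None = None
               ) -> None:
    """Directed weighted GraphML export with construct node attributes."""
    G = nx.DiGraph()
    for nid, cons in zip(result.node_ids, result.node_constructs):
        G.add_node(nid, construct=cons)
    if edges is not None:
        pairs = [(e.source, e.target, e.weight)
                 for e in edges.edges + edges.autoregressive]
    else:
        pairs = [(result.node_ids[i], result.node_ids[j],
                  float(result.weights[i, j]))
                 for i in range(result.n_nodes)
                 for j in range(result.n_nodes)
                 if result.weights[i, j] != 0.0]
    for s, t, w in pairs:
        G.add_edge(s, t, weight=w)
    nx.write_graphml(G, path)


def plot_network(result: CLPNResult, edges: EdgeList, path) -> None:
    """Basic static plot of the thresholded cross-lagged network."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = nx.DiGraph()
    for nid, cons in zip(result.node_ids, result.node_constructs):
        G.add_node(nid, construct=cons)
    for e in edges.edges:
        G.add_edge(e.source, e.target, weight=e.weight)
    pos = nx.circular_layout(G)
    colors = ["#d62728" if c == result.node_constructs[0] else "#1f77b4"
              for c in result.node_constructs]
    widths = [4.0 * abs(G[u][v]["weight"]) / (edges.threshold or 1.0)
              for u, v in G.edges]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(G, pos=pos, ax=ax, node_color=colors, width=widths,
                     font_size=7, node_size=450, arrowsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_report(report: AnalysisReport, out_dir,
                  overwrite: bool = False) -> dict[str, str]:
    """Write all report artifacts; returns a manifest path -> sha256.

    Refuses to start if the directory is unwritable or any target file
    exists with ``overwrite`` disabled (no partial writes).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = {
        "descriptives.csv": lambda p: report.descriptives.round(6).to_csv(
            p, index=False),
        "paired_tests.csv": lambda p: report.paired_tests.round(6).to_csv(
            p, index=False),
        "edges.csv": lambda p: _edges_csv(report.edges, p),
        "edges.json": lambda p: Path(p).write_text(json.dumps(
            [e.__dict__ for e in report.edges.edges], indent=1)),
        "centrality.csv": lambda p: report.centrality.to_frame().round(
            6).to_csv(p, index=False),
        "network.graphml": lambda p: to_graphml(report.network, p,
                                                report.edges),
        "network.png": lambda p: plot_network(report.network, report.edges,
                                              p),
        "report.json": lambda p: Path(p).write_text(report.to_json()),
    }
    if report.bootstrap is not None:
        targets["bootstrap.csv"] = lambda p: \
            report.bootstrap.summary_frame().round(6).to_csv(p, index=False)
    if report.stability is not None:
        targets["stability.csv"] = lambda p: \
            report.stability.curve_frame().round(6).to_csv(p, index=False)
    if report.subgroups is not None:
        targets["subgroups.csv"] = lambda p: \
            report.subgroups.density_frame().round(6).to_csv(p, index=False)

    existing = [name for name in targets if (out / name).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite existing outputs: {existing}")

    manifest: dict[str, str] = {}
    for name, writer in targets.items():
        path = out / name
        writer(path)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _edges_csv(edges: EdgeList, path) -> None:
    recs = [{"source": e.source, "target": e.target,
             "weight": round(e.weight, 3),
             "is_autoregressive": e.is_autoregressive}
            for e in edges.edges + edges.autoregressive]
    pd.DataFrame(recs, columns=["source", "target", "weight",
                                "is_autoregressive"]).to_csv(path,
                                                             index=False)
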