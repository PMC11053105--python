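"""End-to-end pipeline: table -> correlation matrix -> weighted networks at
nested cutoffs -> cluster overlay -> MST, with figures, machine-readable
twins, and a run report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__, corrnet, mst
from .measure import MeasurementTable

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    table_path: str | Path
    out_dir: str | Path
    cutoffs: tuple[float, ...] = (0.4, 0.6, 0.8)
    overlay_base: float = 0.6
    overlay_fine: float = 0.8
    histogram_bins: int = 20
    zscore_flag: float = 4.0
    drop_outliers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutoffs)
        if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
            raise ValueError("cutoffs must be strictly increasing")
        if not all(0.0 < c < 1.0 for c in cuts):
            raise ValueError("cutoffs must lie in (0, 1)")
        if not self.overlay_fine > self.overlay_base:
            raise ValueError("overlay fine cutoff must exceed the base cutoff")
        self.cutoffs = cuts

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_table(path) -> MeasurementTable:
    """Parse a measurement CSV: incomplete rows are dropped and logged,
    duplicate headers and short tables are errors, constant columns are
    reported via the logger."""
    table = MeasurementTable.from_csv(path)
    if table.n_subjects < 3:
        raise ValueError(f"{path}: fewer than 3 complete rows")
    sd = table.data.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0.0])
    if constant:
        log.warning("%s: constant columns: %s", path, constant)
    return table


def flag_outliers(table: MeasurementTable, z: float = 4.0) -> pd.DataFrame:
    """Report (not remove) cells with |z-score| above the threshold."""
    x = table.data
    zs = (x - x.mean()) / x.std(ddof=0)
    rows, cols = np.nonzero(np.abs(zs.to_numpy()) > z)
    return pd.DataFrame(
        {"subject_id": x.index[rows], "variable": x.columns[cols],
         "z": zs.to_numpy()[rows, cols]})


def _weights_figure(dist: corrnet.EdgeWeightDistribution, corr, path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    iu = np.triu_indices(len(corr.variables), k=1)
    axes[0].hist(corr.r[iu], bins=40, range=(-1, 1), color="#4878a8")
    axes[0].set_xlabel("r")
    axes[0].set_title("signed correlations")
    w = np.sort(dist.weights)
    axes[1].plot(w, np.arange(1, w.size + 1) / w.size, color="#a84848")
    axes[1].set_xlabel("|r|")
    axes[1].set_title("CPDF of |r|")
    axes[2].hist(dist.weights, bins=dist.bin_edges, color="#48a878")
    axes[2].set_xlabel("|r|")
    axes[2].set_title("absolute correlations")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _tree_figure(tree: mst.SpanningTree, path) -> None:
    import networkx as nx

    g = tree.to_graph()
    pos = nx.spring_layout(g, seed=7)
    labels = {n: g.nodes[n].get("cluster", corrnet.UNCLUSTERED) for n in g.nodes}
    palette = sorted({l for l in labels.values() if l != corrnet.UNCLUSTERED})
    cmap = plt.get_cmap("tab10")
    colors = [
        "black" if labels[n] == corrnet.UNCLUSTERED
        else cmap(palette.index(labels[n]) % 10)
        for n in g.nodes
    ]
    fig, ax = plt.subplots(figsize=(9, 9))
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, node_size=120,
                     font_size=5, width=0.8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes artifacts under ``config.out_dir`` and
    returns the run report (also written as report.json / report.txt)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = validate_table(config.table_path)
    outliers = flag_outliers(table, config.zscore_flag)
    if config.drop_outliers and len(outliers):
        bad = set(outliers.subject_id)
        log.warning("dropping %d subjects with |z| > %g", len(bad), config.zscore_flag)
        table = MeasurementTable(table.data.drop(index=sorted(bad)),
                                 units=table.units, numbers=table.numbers)
    outliers.to_csv(out / "outlier_flags.csv", index=False)

    corr = corrnet.pearson_matrix(table)
    corr.to_csv(out / "corr.csv")

    dist = corrnet.weight_distribution(corr, bins=config.histogram_bins,
                                       cutoffs=config.cutoffs)
    pd.DataFrame({"bin_left": dist.bin_edges[:-1], "bin_right": dist.bin_edges[1:],
                  "count": dist.counts}).to_csv(out / "weights_histogram.csv", index=False)
    _weights_figure(dist, corr, out / "weights.png")

    fine_graph = corrnet.threshold_graph(corr, config.overlay_fine)
    fine_clusters = corrnet.connected_components(fine_graph)

    graphs = {}
    for c in config.cutoffs:
        g = corrnet.threshold_graph(corr, c)
        g = corrnet.overlay_clusters(g, fine_clusters)
        tag = f"{c:.2f}".replace(".", "")
        corrnet.graph_to_graphml(g, out / f"network_cut{tag}.graphml")
        corrnet.graph_to_edge_tsv(g, out / f"network_cut{tag}.tsv")
        graphs[c] = g

    dmat = mst.correlation_to_distance(corr)
    tree = mst.kruskal_mst(dmat)
    overlay = graphs.get(config.overlay_base) or corrnet.overlay_clusters(
        corrnet.threshold_graph(corr, config.overlay_base), fine_clusters)
    labels = {n: overlay.nodes[n]["cluster"] for n in overlay.nodes}
    tree = mst.annotate_tree(tree, fine_clusters, labels=labels)
    tree.to_tsv(out / "mst.tsv")
    mst.tree_to_graphml(tree, out / "mst.graphml")
    (out / "mst.newick").write_text(tree.to_newick() + "\n")
    _tree_figure(tree, out / "mst.png")

    cluster_table = {
        f"C{k}": members
        for k, (_, members) in enumerate(
            sorted(fine_clusters.clusters().items(),
                   key=lambda kv: (-len(kv[1]), kv[1][0])), start=1)
    }
    clique_checks = {}
    base_graph = graphs.get(config.overlay_fine, fine_graph)
    for label, members in cluster_table.items():
        ok, missing = corrnet.is_clique(fine_graph, members)
        clique_checks[label] = {"clique": ok, "missing_pairs": [list(p) for p in missing]}

    report = {
        "tool": "cephnet",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
                   for k, v in vars(config).items()},
        "config_hash": config.digest(),
        "n_subjects": table.n_subjects,
        "n_variables": len(table.variables),
        "rejected_subjects": table.rejected_subjects,
        "pair_count": corrnet.pair_count(len(table.variables)),
        "fraction_at_or_above": {f"{c:g}": dist.fraction_at_or_above[c]
                                 for c in config.cutoffs},
        "edges_at_cutoff": {f"{c:g}": graphs[c].number_of_edges()
                            for c in config.cutoffs},
        "clusters": cluster_table,
        "n_clusters": len(cluster_table),
        "isolated_nodes": fine_clusters.isolated(),
        "clique_checks": clique_checks,
        "outlier_flags": int(len(outliers)),
        "mst": {"n_edges": len(tree.edges),
                "total_distance": tree.total_distance,
                "inter_cluster_edges": sum(bool(e.inter_cluster) for e in tree.edges)},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(render_report(report))
    (out / "clusters.json").write_text(json.dumps(cluster_table, indent=2))
    return report


def render_report(report: dict) -> str:
    lines = [
        f"cephnet {report['version']} run report (config {report['config_hash']})",
        f"subjects: {report['n_subjects']}   variables: {report['n_variables']}"
        f"   pairs: {report['pair_count']}",
        "fraction of pairs at or above cutoff:",
    ]
    for c, f in report["fraction_at_or_above"].items():
        lines.append(f"  |r| >= {c}: {100 * f:.1f}%  ({report['edges_at_cutoff'][c]} edges)")
    lines.append(f"clusters at fine cutoff: {report['n_clusters']}")
    for label, members in report["clusters"].items():
        clique = report["clique_checks"][label]["clique"]
        lines.append(f"  {label} ({'clique' if clique else 'not a clique'}, "
                     f"{len(members)} vars): {', '.join(members)}")
    lines.append(f"isolated nodes: {len(report['isolated_nodes'])}")
    m = report["mst"]
    lines.append(f"MST: {m['n_edges']} edges, total distance {m['total_distance']:.3f}, "
                 f"{m['inter_cluster_edges']} inter-cluster edges")
    return "\n".join(lines) + "\n"
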