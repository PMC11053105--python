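"""Absolute-Pearson correlation networks.

The signed Pearson matrix is retained for reporting, but network
topology is always built from |r|: variable sign conventions differ
between measurement schemes, so only the magnitude of association is
comparable across pairs.  Cutoffs are inclusive (an edge is kept when
|r| >= cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .measure import MeasurementTable

UNCLUSTERED = "unclustered"


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over named variables."""

    variables: list[str]
    r: np.ndarray
    n_subjects: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        v = len(self.variables)
        if self.r.shape != (v, v):
            raise ValueError(f"matrix shape {self.r.shape} != ({v}, {v})")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValueError("|r| exceeds 1")

    def abs_weights(self) -> np.ndarray:
        """|r| of the V(V-1)/2 distinct pairs (upper triangle, row-major)."""
        iu = np.triu_indices(len(self.variables), k=1)
        return np.abs(self.r[iu])

    def submatrix(self, subset: Sequence[str]) -> "CorrelationMatrix":
        idx = [self._index(v) for v in subset]
        return CorrelationMatrix(list(subset), self.r[np.ix_(idx, idx)], self.n_subjects)

    def _index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def to_csv(self, path) -> None:
        pd.DataFrame(self.r, index=self.variables, columns=self.variables).to_csv(path)

    @classmethod
    def from_csv(cls, path, n_subjects: int = 0) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(list(df.columns), df.to_numpy(float), n_subjects)


@dataclass
class EdgeWeightDistribution:
    """Distribution of |r| over distinct pairs, for cutoff selection."""

    weights: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_at_or_above: dict[float, float]

    def cpdf(self, x: float) -> float:
        """Empirical cumulative probability P(|r| <= x)."""
        return float(np.mean(self.weights <= x))


@dataclass
class ClusterAssignment:
    """Partition of variables into connected components."""

    labels: dict[str, int]
    sizes: dict[int, int]

    @property
    def components(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.labels.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(members) for cid, members in out.items()}

    def clusters(self) -> dict[int, list[str]]:
        """Components of size >= 2 (the reported clusters)."""
        return {cid: m for cid, m in self.components.items() if len(m) >= 2}

    def isolated(self) -> list[str]:
        return sorted(n for n, cid in self.labels.items() if self.sizes[cid] == 1)


def pearson_matrix(table: MeasurementTable) -> CorrelationMatrix:
    """Pearson correlation matrix of all table columns.

    Requires >= 3 complete rows and no constant column.
    """
    if table.n_subjects < 3:
        raise ValueError("Pearson correlation needs at least 3 subjects")
    x = table.data.to_numpy(float)
    sd = x.std(axis=0)
    constant = [c for c, s in zip(table.variables, sd) if s == 0]
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(table.variables, r, table.n_subjects)


def pair_count(v: int) -> int:
    """Number of unordered variable pairs, v(v-1)/2."""
    if v < 2:
        raise ValueError("pair count needs at least 2 variables")
    return v * (v - 1) // 2


def weight_distribution(corr: CorrelationMatrix, bins: int = 20,
                        cutoffs: Iterable[float] = (0.4, 0.6, 0.8)) -> EdgeWeightDistribution:
    """Histogram / CPDF of |r| over distinct pairs, plus the retained
    fraction at each candidate cutoff (inclusive >=)."""
    w = corr.abs_weights()
    counts, edges = np.histogram(w, bins=bins, range=(0.0, 1.0))
    frac = {float(c): float(np.mean(w >= c)) for c in cutoffs}
    return EdgeWeightDistribution(weights=w, bin_edges=edges, counts=counts,
                                  fraction_at_or_above=frac)


def threshold_graph(corr: CorrelationMatrix, cutoff: float) -> nx.Graph:
    """Undirected graph keeping edges with |r| >= cutoff.

    Every variable appears as a node even if isolated.  Edge attributes:
    ``weight`` = |r|, ``r`` = signed r.  Graph attribute ``cutoff``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    g = nx.Graph(cutoff=float(cutoff))
    g.add_nodes_from(corr.variables)
    v = len(corr.variables)
    for i in range(v):
        for j in range(i + 1, v):
            rij = corr.r[i, j]
            if abs(rij) >= cutoff:
                g.add_edge(corr.variables[i], corr.variables[j],
                           weight=float(abs(rij)), r=float(rij))
    return g


def connected_components(graph: nx.Graph) -> ClusterAssignment:
    """Partition nodes into components; size-1 components are isolated nodes.

    Component ids are assigned by decreasing size, ties broken by the
    lexicographically smallest member, so labels are deterministic.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    labels = {node: cid for cid, comp in enumerate(comps) for node in comp}
    sizes = {cid: len(comp) for cid, comp in enumerate(comps)}
    return ClusterAssignment(labels=labels, sizes=sizes)


def is_clique(graph: nx.Graph, nodes: Iterable[str]) -> tuple[bool, list[tuple[str, str]]]:
    """Whether every pair in *nodes* is an edge; if not, list missing pairs."""
    nodes = sorted(set(nodes))
    unknown = [n for n in nodes if n not in graph]
    if unknown:
        raise KeyError(f"nodes not in graph: {unknown}")
    missing = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if not graph.has_edge(nodes[i], nodes[j])
    ]
    return (not missing), missing


def overlay_clusters(base: nx.Graph, fine: ClusterAssignment) -> nx.Graph:
    """Annotate a coarser-cutoff graph with cluster labels found at a
    finer (higher) cutoff.

    Nodes belonging to fine clusters of size >= 2 get labels "C1",
    "C2", ... (decreasing cluster size); all other nodes are labeled
    ``"unclustered"``.
    """
    if set(base.nodes) != set(fine.labels):
        raise ValueError("overlay: variable sets differ between graph and clusters")
    g = base.copy()
    clusters = fine.clusters()
    order = sorted(clusters, key=lambda cid: (-len(clusters[cid]), clusters[cid][0]))
    label_of: dict[str, str] = {}
    for k, cid in enumerate(order, start=1):
        for node in clusters[cid]:
            label_of[node] = f"C{k}"
    for node in g.nodes:
        g.nodes[node]["cluster"] = label_of.get(node, UNCLUSTERED)
    return g


def subnetwork_compare(corr: CorrelationMatrix, subset: Sequence[str], cutoff: float,
                       reference_edges: Iterable[tuple[str, str]]) -> dict[str, list[tuple[str, str]]]:
    """Compare the unweighted subset network at *cutoff* with a reference
    edge list; returns matched / extra / missing pairs (sorted)."""
    sub = corr.submatrix(list(subset))
    own = {tuple(sorted(e)) for e in threshold_graph(sub, cutoff).edges}
    ref = set()
    for a, b in reference_edges:
        for n in (a, b):
            if n not in subset:
                raise KeyError(f"reference edge names unknown variable {n!r}")
        ref.add(tuple(sorted((a, b))))
    return {
        "matched": sorted(own & ref),
        "extra": sorted(own - ref),
        "missing": sorted(ref - own),
    }


def graph_to_edge_tsv(graph: nx.Graph, path) -> None:
    """Plain edge list: var1, var2, r, abs_r (tab-separated)."""
    rows = [
        {"var1": u, "var2": v, "r": d.get("r", np.nan), "abs_r": d.get("weight", np.nan)}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["var1", "var2", "r", "abs_r"]).to_csv(
        path, sep="\t", index=False)


def graph_to_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
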