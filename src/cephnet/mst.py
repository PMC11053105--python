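"""Minimum spanning tree over the correlation-derived distance d = 1 - |r|.

The MST is computed on the complete distance matrix (no cutoff), using
Kruskal's algorithm with an explicit union-find.  Ties between equal
distances are broken by ascending lexicographic (var1, var2) pair so the
output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corrnet import ClusterAssignment, CorrelationMatrix, UNCLUSTERED


@dataclass
class DistanceMatrix:
    """Symmetric matrix d = 1 - |r| with zero diagonal, entries in [0, 1]."""

    variables: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        v = len(self.variables)
        if self.d.shape != (v, v):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({v}, {v})")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class TreeEdge:
    var1: str
    var2: str
    distance: float
    abs_r: float
    inter_cluster: bool | None = None


@dataclass
class SpanningTree:
    """MST edge list plus optional cluster annotations."""

    variables: list[str]
    edges: list[TreeEdge]
    node_labels: dict[str, str] = field(default_factory=dict)

    @property
    def total_distance(self) -> float:
        return float(sum(e.distance for e in self.edges))

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.var1, e.var2))) for e in self.edges}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.variables)
        for e in self.edges:
            g.add_edge(e.var1, e.var2, distance=e.distance, abs_r=e.abs_r,
                       **({"inter_cluster": e.inter_cluster}
                          if e.inter_cluster is not None else {}))
        for node, label in self.node_labels.items():
            g.nodes[node]["cluster"] = label
        return g

    def to_tsv(self, path) -> None:
        rows = [
            {"var1": e.var1, "var2": e.var2, "d": e.distance, "abs_r": e.abs_r,
             "inter_cluster": e.inter_cluster}
            for e in self.edges
        ]
        pd.DataFrame(rows, columns=["var1", "var2", "d", "abs_r", "inter_cluster"]).to_csv(
            path, sep="\t", index=False)

    def to_newick(self) -> str:
        """Newick-like nested rendering rooted at the highest-degree node."""
        g = self.to_graph()
        root = max(sorted(g.nodes), key=lambda n: g.degree(n))

        def render(node: str, parent: str | None) -> str:
            children = sorted(n for n in g.neighbors(node) if n != parent)
            label = node.replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")
            if not children:
                return label
            inner = ",".join(render(c, node) for c in children)
            return f"({inner}){label}"

        return render(root, None) + ";"


class _UnionFind:
    """Union-find with path compression and union by rank."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.rank[ri] < self.rank[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        if self.rank[ri] == self.rank[rj]:
            self.rank[ri] += 1
        return True


def correlation_to_distance(corr: CorrelationMatrix) -> DistanceMatrix:
    """d_ij = 1 - |r_ij| (sign-blind), d_ii = 0."""
    d = 1.0 - np.abs(corr.r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(corr.variables), d)


def kruskal_mst(dist: DistanceMatrix) -> SpanningTree:
    """Kruskal MST of the complete graph defined by the distance matrix.

    Edges are scanned in ascending (distance, lexicographic pair) order;
    cycles are rejected via union-find.  Output has exactly V - 1 edges.
    """
    v = len(dist.variables)
    if v < 2:
        raise ValueError("MST needs at least 2 variables")
    order = sorted(range(v), key=lambda i: dist.variables[i])
    candidates = [
        (float(dist.d[order[i], order[j]]),
         dist.variables[order[i]], dist.variables[order[j]],
         order[i], order[j])
        for i in range(v)
        for j in range(i + 1, v)
    ]
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    uf = _UnionFind(v)
    edges: list[TreeEdge] = []
    for d, name_i, name_j, i, j in candidates:
        if uf.union(i, j):
            edges.append(TreeEdge(name_i, name_j, d, 1.0 - d))
            if len(edges) == v - 1:
                break
    assert len(edges) == v - 1, "complete graph must yield a spanning tree"
    return SpanningTree(variables=list(dist.variables), edges=edges)


def annotate_tree(tree: SpanningTree, clusters: ClusterAssignment,
                  labels: dict[str, str] | None = None) -> SpanningTree:
    """Attach cluster labels to tree nodes and flag inter-cluster edges.

    ``labels`` optionally maps node -> display label (e.g. from an
    overlay graph); by default clusters of size >= 2 become "C1",
    "C2", ... and singletons are "unclustered".  Edges whose endpoints
    carry different labels, or touch an unclustered node, are flagged
    inter-cluster: these are the key links between variable groups.
    """
    if set(tree.variables) != set(clusters.labels):
        raise ValueError("annotate_tree: variable sets differ")
    if labels is None:
        ordered = sorted(clusters.clusters().items(),
                         key=lambda kv: (-len(kv[1]), kv[1][0]))
        labels = {}
        for k, (_, members) in enumerate(ordered, start=1):
            for node in members:
                labels[node] = f"C{k}"
    node_labels = {n: labels.get(n, UNCLUSTERED) for n in tree.variables}
    edges = [
        TreeEdge(e.var1, e.var2, e.distance, e.abs_r,
                 inter_cluster=(node_labels[e.var1] != node_labels[e.var2]
                                or node_labels[e.var1] == UNCLUSTERED))
        for e in tree.edges
    ]
    return SpanningTree(variables=list(tree.variables), edges=edges,
                        node_labels=node_labels)


def tree_to_graphml(tree: SpanningTree, path) -> None:
    g = tree.to_graph()
    nx.write_graphml(g, path)
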