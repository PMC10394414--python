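"""Similarity network (>50 % edges) and catalogue dendrogram.

The network is an undirected simple graph with one node per catalogued
cluster; an edge connects a pair iff their percent similarity strictly
exceeds the threshold. The dendrogram is a UPGMA (average-linkage)
agglomeration on the distance d = 100 − similarity, serialized as
Newick with ultrametric branch lengths.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .records import SimilarityMatrix

PathLike = Union[str, Path]

NODE_ATTR_KEYS = ("pks_type", "known_product", "phylum")


def build_network(
    matrix: SimilarityMatrix,
    threshold: float = 50.0,
    node_attrs: Optional[Mapping[str, Mapping]] = None,
) -> nx.Graph:
    """Graph with an edge per pair scoring strictly above ``threshold``."""
    if threshold >= 100:
        warnings.warn("threshold >= 100: the network will have no edges")
    g = nx.Graph()
    attrs = node_attrs or {}
    for cid in matrix.ids:
        a = attrs.get(cid, {})
        g.add_node(
            cid,
            pks_type=str(a.get("pks_type") or ""),
            known_product=bool(a.get("known_product", False)),
            phylum=str(a.get("phylum") or ""),
        )
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            score = float(matrix.scores[i, j])
            if score > threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j], weight=score)
    return g


def connected_components(graph: nx.Graph) -> tuple[list[set], list[str]]:
    """Partition into components; singletons reported separately as the
    disconnected (deorphanization-candidate) list."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda s: (-len(s), min(s)))
    disconnected = sorted(n for c in comps if len(c) == 1 for n in c)
    return comps, disconnected


def export_network(graph: nx.Graph, path: PathLike, format: str = "graphml") -> None:
    """Write the network as GraphML (typed attributes), SIF or edge TSV."""
    path = Path(path)
    if format == "graphml":
        # deterministic node/edge ordering
        h = nx.Graph()
        h.add_nodes_from(sorted(graph.nodes(data=True)))
        h.add_edges_from(
            sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))
        )
        nx.write_graphml(h, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen = set()
            for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges()):
                fh.write(f"{u}\tsim\t{v}\n")
                seen.update((u, v))
            for n in sorted(graph.nodes()):
                if n not in seen:
                    fh.write(f"{n}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tsimilarity\n")
            for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges()):
                fh.write(f"{u}\t{v}\t{graph[u][v]['weight']:.4f}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_graphml(path: PathLike) -> nx.Graph:
    return nx.read_graphml(str(path))


def build_dendrogram(matrix: SimilarityMatrix) -> "DendrogramNode":
    """UPGMA tree over d = 100 − similarity; leaves are cluster ids."""
    if len(matrix) < 2:
        raise ValueError("dendrogram requires at least two clusters")
    d = 100.0 - matrix.scores
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return _tree_from_linkage(linkage, matrix.ids)


class DendrogramNode:
    """Minimal rooted-tree node with heights for ultrametric Newick export."""

    __slots__ = ("name", "height", "children")

    def __init__(self, name: Optional[str], height: float, children: Sequence["DendrogramNode"] = ()):
        self.name = name
        self.height = height
        self.children = list(children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner(parent_height=None) + ";"

    def _newick_inner(self, parent_height: Optional[float]) -> str:
        if self.is_leaf:
            label = self.name
        else:
            label = "(" + ",".join(c._newick_inner(self.height) for c in self.children) + ")"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:.6f}"

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (ultrametric: all equal to root height)."""
        depths: dict[str, float] = {}

        def walk(node: "DendrogramNode", acc: float):
            if node.is_leaf:
                depths[node.name] = acc
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self, 0.0)
        return depths


def _tree_from_linkage(linkage: np.ndarray, ids: Sequence[str]) -> DendrogramNode:
    n = len(ids)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(ids[i], 0.0) for i in range(n)
    }
    for k, (a, b, dist, _count) in enumerate(linkage):
        nodes[n + k] = DendrogramNode(None, dist / 2.0, [nodes[int(a)], nodes[int(b)]])
    return nodes[n + len(linkage) - 1]


def write_newick(tree: DendrogramNode, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
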