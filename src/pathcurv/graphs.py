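"""Pathway graph input/output, shortest-path distances, synthetic generators.

Pathway graphs are simple undirected graphs over string node identifiers:
self-loops are dropped, duplicate and reversed edges collapse to one, and
node order is fixed lexicographically so that every seeded downstream
operation is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

#: sentinel for node pairs in different connected components
UNREACHABLE = -1


@dataclass(frozen=True)
class PathwayGraph:
    """Simple undirected graph: sorted node identifiers plus canonical edges."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(cls, edges, extra_nodes=()) -> "PathwayGraph":
        """Build a graph, canonicalizing edge order and dropping self-loops."""
        clean = set()
        self_loops = 0
        nodes = set(map(str, extra_nodes))
        for u, v in edges:
            u, v = str(u), str(v)
            nodes.update((u, v))
            if u == v:
                self_loops += 1
                continue
            clean.add((u, v) if u < v else (v, u))
        if self_loops:
            logger.info("dropped %d self-loop(s)", self_loops)
        return cls(tuple(sorted(nodes)), frozenset(clean))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.nodes)}

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix in node order."""
        idx = self.node_index()
        A = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            A[idx[u], idx[v]] = 1.0
            A[idx[v], idx[u]] = 1.0
        return A


@dataclass(frozen=True)
class GraphDistances:
    """All-pairs shortest-path matrix; unreachable pairs hold ``UNREACHABLE``."""

    nodes: tuple[str, ...]
    matrix: np.ndarray

    def __getitem__(self, pair) -> int:
        idx = {u: i for i, u in enumerate(self.nodes)}
        u, v = pair
        return int(self.matrix[idx[u], idx[v]])

    @property
    def all_reachable(self) -> bool:
        return not np.any(self.matrix == UNREACHABLE)


def read_graph(path, format: str = "edgelist") -> PathwayGraph:
    """Read a pathway graph from disk.

    ``edgelist`` lines hold two whitespace-separated identifiers.
    ``pathway_commons_txt`` lines hold three tab-separated columns
    (participant_a, interaction_type, participant_b); the interaction type is
    ignored and a header line starting with ``PARTICIPANT`` is tolerated.
    Malformed lines raise ``ValueError`` with their line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if format == "edgelist":
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
                edges.append((parts[0], parts[1]))
            elif format == "pathway_commons_txt":
                parts = line.split("\t")
                if lineno == 1 and parts[0].upper().startswith("PARTICIPANT"):
                    continue
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"unknown format {format!r}")
    return PathwayGraph.from_edges(edges)


def write_edgelist(g: PathwayGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")


def shortest_path_distances(g: PathwayGraph) -> GraphDistances:
    """Exact unweighted breadth-first all-pairs shortest-path distances."""
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    idx = g.node_index()
    rows, cols = [], []
    for u, v in g.edges:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(g.n_nodes, g.n_nodes))
    D = _csgraph_shortest_path(A, method="D", unweighted=True, directed=False)
    out = np.where(np.isinf(D), UNREACHABLE, D).astype(int)
    return GraphDistances(g.nodes, out)


def largest_component(g: PathwayGraph) -> PathwayGraph:
    """Restrict to the largest connected component.

    Graph-distance-based losses are undefined for unreachable pairs, so
    embedding and distortion computations operate on this restriction.
    Isolated nodes are dropped as part of the same rule.
    """
    nxg = g.to_networkx()
    if nxg.number_of_nodes() == 0:
        return g
    comps = list(nx.connected_components(nxg))
    best = max(comps, key=lambda c: (len(c), sorted(c)[0]))
    dropped = g.n_nodes - len(best)
    if dropped:
        logger.warning("restricting to largest component: dropped %d node(s)", dropped)
    edges = [(u, v) for u, v in g.edges if u in best]
    return PathwayGraph.from_edges(edges, extra_nodes=best if len(best) > 1 else best)


def is_connected(g: PathwayGraph) -> bool:
    return g.n_nodes > 0 and nx.is_connected(g.to_networkx())


def generate_synthetic(kind: str, params: dict | None = None, seed: int = 0) -> PathwayGraph:
    """Seeded synthetic graphs with known geometric character.

    Kinds: ``balanced_tree`` (branching, depth), ``cycle`` (n), ``grid``
    (rows, cols), ``tree_of_cycles`` (branching, depth, cycle_len) — a
    balanced tree whose every node is replaced by a small cycle — and
    ``erdos_renyi`` (n, p).  Node identifiers are zero-padded integers so
    lexicographic and construction order agree.
    """
    params = dict(params or {})
    if kind == "balanced_tree":
        b, d = int(params.get("branching", 2)), int(params.get("depth", 4))
        nxg = nx.balanced_tree(b, d)
    elif kind == "cycle":
        nxg = nx.cycle_graph(int(params.get("n", 20)))
    elif kind == "grid":
        rows, cols = int(params.get("rows", 4)), int(params.get("cols", 5))
        nxg = nx.convert_node_labels_to_integers(nx.grid_2d_graph(rows, cols))
    elif kind == "tree_of_cycles":
        b = int(params.get("branching", 2))
        d = int(params.get("depth", 2))
        k = int(params.get("cycle_len", 5))
        tree = nx.balanced_tree(b, d)
        nxg = nx.Graph()
        for node in tree.nodes:
            ring = [(node, i) for i in range(k)]
            nxg.add_edges_from(zip(ring, ring[1:] + ring[:1]))
        for u, v in tree.edges:
            nxg.add_edge((u, 0), (v, 0))
        nxg = nx.convert_node_labels_to_integers(nxg, ordering="sorted")
    elif kind == "erdos_renyi":
        n, p = int(params.get("n", 60)), float(params.get("p", 0.1))
        nxg = nx.gnp_random_graph(n, p, seed=int(seed))
    elif kind == "planted_partition":
        n = int(params.get("n", 60))
        blocks = int(params.get("blocks", 2))
        p_in = float(params.get("p_in", 0.3))
        p_out = float(params.get("p_out", 0.02))
        sizes = [n // blocks] * blocks
        sizes[0] += n - sum(sizes)
        nxg = nx.stochastic_block_model(
            sizes,
            [[p_in if i == j else p_out for j in range(blocks)] for i in range(blocks)],
            seed=int(seed),
        )
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    width = max(3, len(str(nxg.number_of_nodes())))
    edges = [(f"n{u:0{width}d}", f"n{v:0{width}d}") for u, v in nxg.edges]
    names = [f"n{u:0{width}d}" for u in nxg.nodes]
    return PathwayGraph.from_edges(edges, extra_nodes=names)
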