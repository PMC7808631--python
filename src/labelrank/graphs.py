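"""Contact networks: representation, synthetic generators and edge-list I/O.

A contact network is a static, simple, undirected, unweighted, connected
graph whose nodes are the individuals a pathogen can pass between. Nodes
are always relabelled to contiguous integer ids ``0..n-1`` internally; a
reader that accepts arbitrary integer ids keeps the original labels in
:attr:`ContactNetwork.id_map`.

The three synthetic families used for benchmarking are the classic trio:
Erdős–Rényi G(n, m) random graphs, Barabási–Albert preferential-attachment
scale-free graphs, and Watts–Strogatz small-world rewired ring lattices.
The G(n, m) variant (exact edge count) is used for ER so that the printed
benchmark edge counts are matched exactly rather than in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import EdgeListFormatError, GraphGenerationError

__all__ = [
    "ContactNetwork",
    "generate_er",
    "generate_ba",
    "generate_ws",
    "read_edgelist",
    "write_edgelist",
    "geodesic_distance",
]

#: attempts before a connectivity-constrained generator gives up
MAX_GENERATION_ATTEMPTS = 1000


@dataclass(frozen=True)
class ContactNetwork:
    """An undirected, unweighted, simple, connected contact graph.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph` with nodes ``0..n-1``.
    id_map
        Optional mapping from internal id to the original label found in
        an input file; identity when the network was generated in-package.
    """

    graph: nx.Graph
    id_map: dict[int, int] | None = field(default=None, compare=False)

    def __post_init__(self):
        g = self.graph
        n = g.number_of_nodes()
        if n < 2:
            raise ValueError(f"contact network needs >= 2 nodes, got {n}")
        if sorted(g.nodes) != list(range(n)):
            raise ValueError("node ids must be contiguous integers 0..n-1")
        if any(g.has_edge(u, u) for u in g.nodes):
            raise ValueError("self-loops are not allowed")
        if not nx.is_connected(g):
            raise ValueError("contact network must be connected")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> np.ndarray:
        """Degree of every node as a length-n integer vector."""
        return np.array([d for _, d in sorted(self.graph.degree)], dtype=np.int64)

    def adjacency(self) -> sp.csr_array:
        """Binary adjacency matrix W in CSR form (zero diagonal, symmetric).

        Cached: the graph is immutable once wrapped.
        """
        cached = getattr(self, "_adjacency", None)
        if cached is None:
            cached = sp.csr_array(
                nx.to_scipy_sparse_array(self.graph, nodelist=range(self.n), dtype=np.float64)
            )
            object.__setattr__(self, "_adjacency", cached)
        return cached

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))

    def validate_node(self, i: int) -> None:
        if not (isinstance(i, (int, np.integer)) and 0 <= i < self.n):
            raise ValueError(f"unknown node id {i!r} (valid: 0..{self.n - 1})")


def _until_connected(build, what: str) -> nx.Graph:
    for _ in range(MAX_GENERATION_ATTEMPTS):
        g = build()
        if nx.is_connected(g):
            return g
    raise GraphGenerationError(
        f"{what}: no connected draw in {MAX_GENERATION_ATTEMPTS} attempts"
    )


def generate_er(n: int, m: int, seed: int) -> ContactNetwork:
    """Erdős–Rényi G(n, m): exactly m uniform edges, redrawn until connected."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not (0 < m <= n * (n - 1) // 2):
        raise ValueError(f"m must satisfy 0 < m <= n(n-1)/2, got {m}")
    if m < n - 1:
        raise GraphGenerationError(f"G({n},{m}) cannot be connected: m < n-1")
    rng = np.random.default_rng(seed)
    g = _until_connected(
        lambda: nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31))),
        f"ER G({n},{m})",
    )
    return ContactNetwork(g)


def generate_ba(n: int, m_attach: int, seed: int) -> ContactNetwork:
    """Barabási–Albert preferential attachment.

    Growth starts from ``m_attach`` seed nodes that the first arriving node
    connects to all at once (a star), then every later node attaches
    ``m_attach`` edges preferentially; the result is connected by
    construction with exactly ``m_attach * (n - m_attach)`` edges.
    """
    if not (1 <= m_attach < n):
        raise ValueError(f"need 1 <= m_attach < n, got m_attach={m_attach}, n={n}")
    g = nx.barabasi_albert_graph(n, m_attach, seed=seed)
    return ContactNetwork(g)


def generate_ws(n: int, k: int, p_rewire: float, seed: int) -> ContactNetwork:
    """Watts–Strogatz ring lattice with rewiring; exactly n*k/2 edges."""
    if k % 2 != 0:
        raise ValueError(f"ring degree k must be even, got {k}")
    if not (0 < k < n):
        raise ValueError(f"need 0 < k < n, got k={k}, n={n}")
    if not (0.0 <= p_rewire <= 1.0):
        raise ValueError(f"rewiring probability must be in [0, 1], got {p_rewire}")
    rng = np.random.default_rng(seed)
    g = _until_connected(
        lambda: nx.watts_strogatz_graph(n, k, p_rewire, seed=int(rng.integers(2**31))),
        f"WS({n},{k},{p_rewire})",
    )
    return ContactNetwork(g)


def read_edgelist(path) -> ContactNetwork:
    """Read a whitespace-separated integer edge list ('#' starts a comment).

    Arbitrary integer ids are relabelled to 0..n-1 (sorted order of the
    original ids); the original labels are kept in ``id_map``.
    """
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected two integer columns, got {raw!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: unparsable integers in {raw!r}"
                ) from None
            if u == v:
                raise EdgeListFormatError(f"{path}:{lineno}: self-loop on node {u}")
            edges.append((u, v))
    if not edges:
        raise EdgeListFormatError(f"{path}: no edges found")
    original = sorted({x for e in edges for x in e})
    to_internal = {orig: i for i, orig in enumerate(original)}
    g = nx.Graph()
    g.add_nodes_from(range(len(original)))
    g.add_edges_from((to_internal[u], to_internal[v]) for u, v in edges)
    if not nx.is_connected(g):
        k = nx.number_connected_components(g)
        raise EdgeListFormatError(f"{path}: graph is disconnected ({k} components)")
    return ContactNetwork(g, id_map=dict(enumerate(original)))


def write_edgelist(network: ContactNetwork, path) -> None:
    """Write the canonical edge list: one 'u v' pair per line, u < v, sorted."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{u} {v}\n")


def geodesic_distance(network: ContactNetwork, u: int, v: int) -> int:
    """Hop count of the shortest path between u and v (0 iff u == v)."""
    network.validate_node(u)
    network.validate_node(v)
    return nx.shortest_path_length(network.graph, u, v)
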