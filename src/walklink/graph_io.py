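"""Graph containers, edge-list I/O, and the query-counted graph oracle.

A network here is always a simple, undirected, unweighted graph: a
symmetric 0/1 adjacency matrix with zero diagonal.  All algorithms in this
package see the graph either directly (:class:`Network`) or through the
*general graph model* oracle (:class:`GGMOracle`), which mediates access
via three unit-cost query types — degree, l-th neighbour, and vertex-pair
— and counts every call.  The query counters are the instrument with which
the sampling algorithms' query complexities are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class _NotPresent:
    """Sentinel returned by a neighbour query with l > k_v."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_PRESENT"

    def __bool__(self) -> bool:
        return False


#: Sentinel answer of a neighbour query whose index exceeds the degree.
NOT_PRESENT = _NotPresent()


class Network:
    """Simple undirected unweighted graph on nodes 0..N-1.

    Parameters
    ----------
    node_count:
        Number of nodes N (isolated nodes allowed).
    edges:
        Iterable of node pairs.  Duplicates and orientation are collapsed;
        self-loops are rejected.

    Neighbour lists are stored sorted ascending, so the l-th neighbour
    ``Gamma_l(v)`` (1-based l) is well defined and deterministic.
    """

    __slots__ = ("_n", "_edges", "_neighbours", "_degrees", "_adj", "labels")

    def __init__(self, node_count: int, edges: Iterable[tuple[int, int]],
                 labels: Sequence | None = None):
        n = int(node_count)
        if n <= 0:
            raise ValueError("node_count must be positive")
        edge_set: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop ({u},{u}) not allowed in a simple graph")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for N={n}")
            edge_set.add((min(u, v), max(u, v)))
        self._n = n
        self._edges = frozenset(edge_set)
        nbrs: list[list[int]] = [[] for _ in range(n)]
        for u, v in edge_set:
            nbrs[u].append(v)
            nbrs[v].append(u)
        self._neighbours = tuple(np.array(sorted(a), dtype=np.int64) for a in nbrs)
        self._degrees = np.array([len(a) for a in self._neighbours], dtype=np.int64)
        self._adj = None
        #: original node labels, index -> label (identity if none given)
        self.labels = list(labels) if labels is not None else list(range(n))

    # -- basic accessors ---------------------------------------------------

    @property
    def node_count(self) -> int:
        return self._n

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """Unordered edge set as (min, max) pairs."""
        return self._edges

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    @property
    def degrees(self) -> np.ndarray:
        return self._degrees

    def degree(self, v: int) -> int:
        self._check_node(v)
        return int(self._degrees[v])

    def neighbours(self, v: int) -> np.ndarray:
        """Sorted neighbour array Gamma(v)."""
        self._check_node(v)
        return self._neighbours[v]

    def neighbour(self, v: int, l: int):
        """l-th neighbour of v, 1-based; NOT_PRESENT if l > k_v."""
        self._check_node(v)
        if l < 1:
            raise ValueError("neighbour index l is 1-based")
        if l > self._degrees[v]:
            return NOT_PRESENT
        return int(self._neighbours[v][l - 1])

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (built lazily, cached)."""
        if self._adj is None:
            a = np.zeros((self._n, self._n), dtype=np.int64)
            for u, v in self._edges:
                a[u, v] = 1
                a[v, u] = 1
            self._adj = a
        return self._adj

    def has_edge(self, u: int, v: int) -> bool:
        self._check_node(u)
        self._check_node(v)
        return (min(u, v), max(u, v)) in self._edges

    @property
    def k_av(self) -> float:
        """Average degree 2|E|/N."""
        return 2.0 * self.edge_count / self._n

    @property
    def k_max(self) -> int:
        return int(self._degrees.max()) if self._n else 0

    def _check_node(self, v: int) -> None:
        if not (0 <= v < self._n):
            raise IndexError(f"node {v} out of range [0, {self._n})")

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_adjacency(cls, a: np.ndarray) -> "Network":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency entries must be 0/1")
        rows, cols = np.nonzero(np.triu(a))
        return cls(a.shape[0], zip(rows.tolist(), cols.tolist()))

    @classmethod
    def from_networkx(cls, g) -> "Network":
        nodes = sorted(g.nodes())
        index = {u: i for i, u in enumerate(nodes)}
        edges = ((index[u], index[v]) for u, v in g.edges() if u != v)
        return cls(len(nodes), edges, labels=nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self._n))
        g.add_edges_from(self._edges)
        return g

    def __repr__(self) -> str:
        return f"Network(N={self._n}, |E|={self.edge_count})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, Network) and self._n == other._n
                and self._edges == other._edges)

    def __hash__(self) -> int:
        return hash((self._n, self._edges))


@dataclass
class GGMOracle:
    """Query-counted general-graph-model view of a :class:`Network`.

    Three query types, each costing one unit: degree, l-th neighbour, and
    vertex-pair (adjacency entry).  Every call increments exactly one
    counter, including repeated calls with the same arguments — caching is
    the caller's job, never the oracle's.
    """

    network: Network
    degree_queries: int = 0
    neighbour_queries: int = 0
    pair_queries: int = 0

    def degree(self, v: int) -> int:
        k = self.network.degree(v)
        self.degree_queries += 1
        return k

    def neighbour(self, v: int, l: int):
        out = self.network.neighbour(v, l)
        self.neighbour_queries += 1
        return out

    def pair(self, u: int, v: int) -> int:
        self.network._check_node(u)
        self.network._check_node(v)
        self.pair_queries += 1
        return int(self.network.has_edge(u, v))

    @property
    def total_queries(self) -> int:
        return self.degree_queries + self.neighbour_queries + self.pair_queries

    def counter_snapshot(self) -> dict[str, int]:
        return {
            "degree": self.degree_queries,
            "neighbour": self.neighbour_queries,
            "pair": self.pair_queries,
            "total": self.total_queries,
        }


# wrapper functions matching the operation-level surface

def oracle_degree(oracle: GGMOracle, v: int) -> int:
    return oracle.degree(v)


def oracle_neighbour(oracle: GGMOracle, v: int, l: int):
    return oracle.neighbour(v, l)


def oracle_pair(oracle: GGMOracle, u: int, v: int) -> int:
    return oracle.pair(u, v)


def good_link_matrix(network: Network) -> np.ndarray:
    """Mask of pairs useful for link prediction: G = J - (A + I).

    ``G_ij = 1`` exactly when ``A_ij = 0`` and ``i != j`` — the ordered
    pairs where a new link could be predicted.  Symmetric, zero diagonal.
    """
    n = network.node_count
    g = np.ones((n, n), dtype=np.int64) - network.adjacency - np.eye(n, dtype=np.int64)
    return g


# -- edge-list and adjacency I/O ------------------------------------------


class EdgeListError(ValueError):
    """Raised for malformed edge-list input."""


def read_edge_list(path, *, strict: bool = False) -> Network:
    """Read a whitespace-delimited edge list into a :class:`Network`.

    Format: one edge per line as two integer tokens; ``#`` starts a
    comment; an optional header line ``N=<int>`` fixes the node count
    (otherwise N = max label + 1 after remapping).  Arbitrary integer
    labels are remapped to contiguous 0-based indices (mapping kept on
    ``Network.labels``) unless a header is present, in which case labels
    must already lie in range.

    Duplicate edges are collapsed silently; self-loops are dropped with a
    warning, or raise if ``strict``.
    """
    path = Path(path)
    raw_edges: list[tuple[int, int]] = []
    declared_n: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if body.upper().startswith("N="):
                try:
                    declared_n = int(body[2:])
                except ValueError:
                    raise EdgeListError(f"{path}:{lineno}: bad header {body!r}")
                continue
            tokens = body.split()
            if len(tokens) != 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected two integer tokens, got {body!r}")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise EdgeListError(
                    f"{path}:{lineno}: non-integer token in {body!r}")
            if u == v:
                if strict:
                    raise EdgeListError(f"{path}:{lineno}: self-loop on node {u}")
                warnings.warn(f"{path}:{lineno}: dropping self-loop on node {u}",
                              stacklevel=2)
                continue
            raw_edges.append((u, v))
    if not raw_edges:
        raise EdgeListError(f"{path}: no edges")
    if declared_n is not None:
        bad = [e for e in raw_edges if max(e) >= declared_n or min(e) < 0]
        if bad:
            raise EdgeListError(f"{path}: edge {bad[0]} outside declared N={declared_n}")
        return Network(declared_n, raw_edges)
    labels = sorted({u for e in raw_edges for u in e})
    if labels[0] >= 0 and labels[-1] == len(labels) - 1:
        # already contiguous and 0-based
        return Network(labels[-1] + 1, raw_edges)
    index = {lab: i for i, lab in enumerate(labels)}
    remapped = [(index[u], index[v]) for u, v in raw_edges]
    return Network(len(labels), remapped, labels=labels)


def write_edge_list(network: Network, path, *, header: bool = True) -> None:
    """Write the edge set, one ``u v`` pair per line (internal 0-based ids)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"N={network.node_count}\n")
        for u, v in sorted(network.edges):
            fh.write(f"{u} {v}\n")


def read_adjacency(path) -> Network:
    """Read a dense whitespace-delimited 0/1 adjacency matrix."""
    a = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return Network.from_adjacency(a)


def write_adjacency(network: Network, path) -> None:
    np.savetxt(path, network.adjacency, fmt="%d")


def read_sparse_triplets(path) -> Network:
    """Read coordinate-format adjacency: one ``row col`` pair per nonzero."""
    return read_edge_list(path)


def write_sparse_triplets(network: Network, path) -> None:
    """Write the nonzero coordinates of A (upper triangle) with an N header."""
    write_edge_list(network, path, header=True)
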