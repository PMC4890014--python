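"""Network substrates for the spatial game.

The population of players occupies the nodes of an undirected graph.  Two
substrates are generated natively — the L×L square lattice with a von
Neumann 4-neighbourhood (periodic or open boundary) and the Barabási–Albert
(BA) preferential-attachment scale-free graph — and arbitrary graphs can be
loaded from plain-text edge lists.

The BA generator is mechanistic: it grows the graph by attaching each new
node to ``m`` distinct existing nodes with probability proportional to their
current degree, starting from a complete graph on ``m`` nodes (the smallest
seed that admits ``m`` distinct attachments).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "NetworkTopology",
    "GraphConnectivityError",
    "EdgeListParseError",
    "build_square_lattice",
    "build_ba_network",
    "network_diameter",
    "read_edge_list",
    "write_edge_list",
    "topology_from_edges",
]


class GraphConnectivityError(ValueError):
    """Raised when an operation requires a connected graph."""


class EdgeListParseError(ValueError):
    """Raised when a plain-text edge list cannot be parsed."""


class _SegmentedAdjacency:
    """CSR-style neighbour arrays with vectorised per-node reductions.

    Stores the concatenated, sorted neighbour lists of all nodes plus the
    segment boundaries, so that per-node quantities (neighbour counts,
    neighbour maxima, random neighbour picks) reduce to ``np.*.reduceat``
    calls over arrays of length 2·E.
    """

    def __init__(self, adjacency: Sequence[frozenset[int]]):
        n = len(adjacency)
        deg = np.fromiter((len(a) for a in adjacency), dtype=np.int64, count=n)
        self.n = n
        self.deg = deg
        self.indptr = np.concatenate(([0], np.cumsum(deg)))
        self.indices = np.fromiter(
            (j for a in adjacency for j in sorted(a)),
            dtype=np.int64,
            count=int(self.indptr[-1]),
        )
        self.seg_id = np.repeat(np.arange(n), deg)
        # reduceat cannot express empty segments; reduce only over non-empty
        # rows (their segments are contiguous) and fill the rest.
        self.nz = np.flatnonzero(deg > 0)
        self.starts = self.indptr[self.nz]

    def count_true(self, node_flags: np.ndarray) -> np.ndarray:
        """Per node, how many neighbours have a True flag."""
        out = np.zeros(self.n, dtype=np.int64)
        if self.indices.size:
            out[self.nz] = np.add.reduceat(
                node_flags[self.indices].astype(np.int64), self.starts
            )
        return out

    def _seg_max(self, values: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(self.n, fill, dtype=float)
        if self.indices.size:
            out[self.nz] = np.maximum.reduceat(values, self.starts)
        return out

    def pick_max(
        self,
        node_values: np.ndarray,
        rng: np.random.Generator,
        eligible: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per node, a neighbour attaining the maximum of ``node_values``.

        Ties are broken uniformly at random.  ``eligible`` optionally
        restricts the candidate set.  Returns ``(choice, ok)``; where
        ``ok[i]`` is False (no neighbours / none eligible) ``choice[i]`` is −1.
        """
        choice = np.full(self.n, -1, dtype=np.int64)
        if not self.indices.size:
            return choice, np.zeros(self.n, dtype=bool)
        v = node_values[self.indices].astype(float)
        if eligible is not None:
            v = np.where(eligible[self.indices], v, -np.inf)
        top = self._seg_max(v, -np.inf)
        # uniform tie-break: random key on the arg-max set, then arg-max the
        # key; the isfinite guard keeps all-ineligible rows (-inf == -inf)
        # from matching
        key = np.where((v == top[self.seg_id]) & np.isfinite(v), rng.random(v.size), -1.0)
        kbest = self._seg_max(key, -1.0)
        ok = kbest >= 0.0
        pos = np.flatnonzero(key == kbest[self.seg_id])
        choice[self.seg_id[pos]] = self.indices[pos]
        choice[~ok] = -1
        return choice, ok

    def pick_uniform(
        self, eligible: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per node, a uniformly random neighbour among the eligible ones."""
        return self.pick_max(np.zeros(self.n), rng, eligible=eligible)


@dataclasses.dataclass(frozen=True)
class NetworkTopology:
    """Immutable undirected graph the population lives on.

    Nodes are the contiguous integers ``0 … node_count−1``; ``adjacency[i]``
    is the frozen neighbour set of node ``i``.  Self-loops are rejected and
    symmetry is enforced at construction.
    """

    node_count: int
    adjacency: tuple[frozenset[int], ...]
    kind: str = "custom"
    boundary: str | None = None

    def __post_init__(self):
        if self.node_count < 1:
            raise ValueError("node_count must be positive")
        if len(self.adjacency) != self.node_count:
            raise ValueError(
                f"adjacency has {len(self.adjacency)} entries for "
                f"{self.node_count} nodes"
            )
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError(f"self-loop at node {i}")
            for j in nbrs:
                if not 0 <= j < self.node_count:
                    raise ValueError(f"node {i} links to out-of-range node {j}")
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric edge {i}-{j}")

    @property
    def segments(self) -> _SegmentedAdjacency:
        seg = self.__dict__.get("_segments")
        if seg is None:
            seg = _SegmentedAdjacency(self.adjacency)
            object.__setattr__(self, "_segments", seg)
        return seg

    @property
    def degrees(self) -> np.ndarray:
        return self.segments.deg

    @property
    def edge_count(self) -> int:
        return int(self.degrees.sum()) // 2

    def neighbors(self, i: int) -> frozenset[int]:
        return self.adjacency[i]

    def sparse_matrix(self) -> csr_matrix:
        seg = self.segments
        data = np.ones(seg.indices.size, dtype=np.int8)
        return csr_matrix(
            (data, seg.indices, seg.indptr), shape=(self.node_count, self.node_count)
        )


def build_square_lattice(side: int, boundary: str = "periodic") -> NetworkTopology:
    """L×L square lattice with the von Neumann 4-neighbourhood.

    ``boundary="periodic"`` wraps both axes (every degree is 4 for L ≥ 3);
    ``boundary="open"`` truncates at the border (corner degree 2, edge
    degree 3).
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    if boundary not in ("periodic", "open"):
        raise ValueError(f"boundary must be 'periodic' or 'open', got {boundary!r}")
    adj: list[set[int]] = [set() for _ in range(side * side)]
    for x in range(side):
        for y in range(side):
            i = x * side + y
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                px, py = x + dx, y + dy
                if boundary == "periodic":
                    px %= side
                    py %= side
                elif not (0 <= px < side and 0 <= py < side):
                    continue
                adj[i].add(px * side + py)
    return NetworkTopology(
        side * side, tuple(frozenset(a) for a in adj), kind="lattice", boundary=boundary
    )


def build_ba_network(
    n: int, m: int, rng: np.random.Generator | np.random.SeedSequence | int
) -> NetworkTopology:
    """Barabási–Albert scale-free graph on ``n`` nodes, ``m`` edges per arrival.

    Growth starts from a complete graph on ``m`` nodes; each arriving node
    attaches to ``m`` distinct existing nodes, each drawn with probability
    proportional to its current degree (sampling from the degree-weighted
    endpoint list, redrawing duplicates).  The result is connected with
    minimum degree ≥ m and mean degree 2·(C(m,2) + m(n−m))/n ≈ 2m.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    adj: list[set[int]] = [set() for _ in range(n)]
    repeated: list[int] = []  # one entry per edge endpoint = degree weights
    for i in range(m):
        for j in range(i + 1, m):
            adj[i].add(j)
            adj[j].add(i)
            repeated += [i, j]
    for v in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            if repeated:
                t = repeated[int(rng.integers(len(repeated)))]
            else:  # m == 1 seed has no edges: first arrival attaches uniformly
                t = int(rng.integers(v))
            targets.add(t)
        for t in targets:
            adj[v].add(t)
            adj[t].add(v)
            repeated += [v, t]
    return NetworkTopology(n, tuple(frozenset(a) for a in adj), kind="scale_free")


def network_diameter(topology: NetworkTopology) -> int:
    """Largest shortest-path length between any pair of nodes.

    Computed by unweighted all-pairs shortest paths (equivalent to repeated
    BFS, and to Floyd–Warshall on an unweighted graph).  Raises
    :class:`GraphConnectivityError` on a disconnected graph.
    """
    if topology.node_count == 1:
        return 0
    mat = topology.sparse_matrix()
    ncomp, _ = connected_components(mat, directed=False)
    if ncomp > 1:
        raise GraphConnectivityError(
            f"graph has {ncomp} components; diameter is undefined"
        )
    dist = shortest_path(mat, method="D", unweighted=True, directed=False)
    return int(dist.max())


def topology_from_edges(
    edges: Iterable[tuple[int, int]],
    node_count: int | None = None,
    kind: str = "custom",
) -> NetworkTopology:
    """Build a topology from an iterable of undirected integer edges."""
    edges = list(edges)
    max_node = max((max(i, j) for i, j in edges), default=-1)
    n = max(max_node + 1, node_count or 0)
    if n < 1:
        raise ValueError("cannot build an empty topology")
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        if i == j:
            raise ValueError(f"self-loop {i}-{j} not allowed")
        adj[i].add(j)
        adj[j].add(i)
    return NetworkTopology(n, tuple(frozenset(a) for a in adj), kind=kind)


def write_edge_list(topology: NetworkTopology, path) -> None:
    """Write a 0-based whitespace-separated edge list (one edge per line).

    A ``# nodes: N`` comment header preserves isolated nodes on round-trip.
    """
    with open(path, "w") as fh:
        fh.write(f"# nodes: {topology.node_count}\n")
        for i in range(topology.node_count):
            for j in sorted(topology.adjacency[i]):
                if i < j:
                    fh.write(f"{i} {j}\n")


def read_edge_list(path) -> NetworkTopology:
    """Parse a plain-text edge list; '#' lines are comments."""
    edges: list[tuple[int, int]] = []
    declared_n = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = re.match(r"#\s*nodes:\s*(\d+)\s*$", line)
                if header:
                    declared_n = int(header.group(1))
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected two tokens, got {len(parts)}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListParseError(
                    f"line {lineno}: non-integer token in {line!r}"
                ) from None
            if i < 0 or j < 0:
                raise EdgeListParseError(f"line {lineno}: negative node id")
            if i == j:
                raise EdgeListParseError(f"line {lineno}: self-loop {i} {j}")
            edges.append((i, j))
    if not edges and declared_n == 0:
        raise EdgeListParseError("no edges or node-count header found")
    return topology_from_edges(edges, node_count=declared_n)
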