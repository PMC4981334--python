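"""Regular graph families used as population structures.

Individuals live on the vertices of a connected k-regular graph.  The
families provided here are the ones used to test the analytical theory:
rings (cycles generalized to even degree), random regular graphs, and
periodic lattices of degree 4 (von Neumann), 6 (triangular/hexagonal
neighborhood), and 8 (Moore).  Lattices use toroidal boundaries, since open
boundaries would break regularity.

Adjacency is stored as a dense ``(N, k)`` integer array of neighbor indices,
which is the layout the simulation kernel consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "RegularGraph",
    "make_ring",
    "make_random_regular",
    "make_lattice",
    "validate_regular",
    "regularity_diagnostics",
    "write_edge_list",
    "read_edge_list",
]

_MAX_RR_RETRIES = 10_000


@dataclass(eq=False)
class RegularGraph:
    """A connected k-regular graph on N vertices (0-based labels)."""

    N: int
    k: int
    adjacency: np.ndarray  # shape (N, k), neighbor lists
    family: str = "custom"
    seed: Optional[int] = None

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency[v]

    def edges(self) -> List[Tuple[int, int]]:
        out = []
        for u in range(self.N):
            for v in self.adjacency[u]:
                if u < v:
                    out.append((u, int(v)))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges())
        return g


def _from_neighbor_sets(nbrs: List[set], k: int, family: str, seed=None) -> RegularGraph:
    N = len(nbrs)
    adj = np.empty((N, k), dtype=np.int32)
    for v, s in enumerate(nbrs):
        if len(s) != k:
            raise ValueError(f"vertex {v} has degree {len(s)}, expected {k}")
        adj[v] = sorted(s)
    return RegularGraph(N=N, k=k, adjacency=adj, family=family, seed=seed)


def make_ring(N: int, k: int) -> RegularGraph:
    """Ring: vertex ``i`` adjacent to its k/2 nearest on each side (mod N).

    ``k = 2`` gives the cycle.  Requires even ``k`` and ``N >= k + 2`` so
    that wrap-around does not create duplicate neighbors.
    """
    if k < 2 or k % 2 != 0:
        raise ValueError(f"ring degree k must be even and >= 2, got {k}")
    if N < k + 2:
        raise ValueError(
            f"ring needs N >= k + 2 (got N={N}, k={k}); smaller N duplicates neighbors"
        )
    half = k // 2
    nbrs = [
        {(i + off) % N for off in range(1, half + 1)}
        | {(i - off) % N for off in range(1, half + 1)}
        for i in range(N)
    ]
    family = "cycle" if k == 2 else "ring"
    return _from_neighbor_sets(nbrs, k, family)


def make_random_regular(N: int, k: int, seed: int) -> RegularGraph:
    """Random simple connected k-regular graph (configuration model).

    Uses pairing with rejection of self-loops/multi-edges, resampling with a
    deterministically advanced seed until the sample is simple and
    connected (cap 10^4 attempts).
    """
    if N <= k:
        raise ValueError(f"need N > k, got N={N}, k={k}")
    if (N * k) % 2 != 0:
        raise ValueError(f"N*k must be even for a k-regular graph (N={N}, k={k})")
    for attempt in range(_MAX_RR_RETRIES):
        g = nx.random_regular_graph(k, N, seed=seed + attempt)
        if nx.is_connected(g):
            nbrs = [set(g.neighbors(v)) for v in range(N)]
            return _from_neighbor_sets(nbrs, k, "random_regular", seed=seed)
    raise RuntimeError(
        f"no connected {k}-regular graph on {N} vertices found in "
        f"{_MAX_RR_RETRIES} attempts"
    )


_LATTICE_OFFSETS = {
    "vn4": [(1, 0), (-1, 0), (0, 1), (0, -1)],
    "hex6": [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)],
    "moore8": [
        (1, 0), (-1, 0), (0, 1), (0, -1),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ],
}


def make_lattice(kind: str, side: int) -> RegularGraph:
    """Periodic lattice on a side x side torus.

    ``vn4``: square lattice, von Neumann neighborhood (degree 4);
    ``hex6``: six-neighbor (triangular) tiling (degree 6);
    ``moore8``: square lattice, Moore neighborhood (degree 8).

    ``moore8`` requires ``side >= 4``: on a 3x3 torus the Moore neighborhood
    collapses onto the complete graph, where diagonal and orthogonal
    directions coincide in the quotient, so we reject it as degenerate.
    """
    if kind not in _LATTICE_OFFSETS:
        raise ValueError(f"unknown lattice kind {kind!r}; choose from {sorted(_LATTICE_OFFSETS)}")
    min_side = 4 if kind == "moore8" else 3
    if side < min_side:
        raise ValueError(f"lattice kind {kind!r} needs side >= {min_side}, got {side}")
    offs = _LATTICE_OFFSETS[kind]
    k = len(offs)
    N = side * side
    nbrs = []
    for x in range(side):
        for y in range(side):
            nbrs.append(
                {((x + dx) % side) * side + ((y + dy) % side) for dx, dy in offs}
            )
    return _from_neighbor_sets(nbrs, k, f"lattice_{kind}")


def regularity_diagnostics(g: RegularGraph, k: Optional[int] = None) -> List[str]:
    """List of violated invariants (empty when the graph is valid)."""
    k = g.k if k is None else k
    problems = []
    adj = g.adjacency
    if adj.shape != (g.N, k):
        problems.append(f"adjacency shape {adj.shape} != ({g.N}, {k})")
        return problems
    nbr_sets = [set(int(x) for x in adj[v]) for v in range(g.N)]
    for v, s in enumerate(nbr_sets):
        if len(s) != k:
            problems.append(f"vertex {v} has {len(s)} distinct neighbors, expected {k}")
        if v in s:
            problems.append(f"vertex {v} has a self-loop")
        if any(not (0 <= u < g.N) for u in s):
            problems.append(f"vertex {v} has an out-of-range neighbor")
    if not problems:
        for v, s in enumerate(nbr_sets):
            for u in s:
                if v not in nbr_sets[u]:
                    problems.append(f"edge ({v}, {u}) is not symmetric")
    if not problems:
        # BFS connectivity
        seen = np.zeros(g.N, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(int(u))
        if not seen.all():
            problems.append(f"graph is disconnected ({int(seen.sum())}/{g.N} reachable)")
    return problems


def validate_regular(g: RegularGraph, k: Optional[int] = None) -> bool:
    """True iff every vertex has exactly ``k`` distinct neighbors, adjacency
    is symmetric without self-loops, and the graph is connected."""
    return not regularity_diagnostics(g, k)


def write_edge_list(g: RegularGraph, path) -> None:
    """Whitespace-separated 0-based ``u v`` pairs, one edge per line."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def read_edge_list(path, family: str = "custom") -> RegularGraph:
    """Read an edge-list file; the graph must be regular and connected."""
    nbrs_map = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u_s, v_s = line.split()
            u, v = int(u_s), int(v_s)
            nbrs_map.setdefault(u, set()).add(v)
            nbrs_map.setdefault(v, set()).add(u)
    if not nbrs_map:
        raise ValueError(f"no edges found in {path}")
    N = max(nbrs_map) + 1
    degrees = {len(nbrs_map.get(v, ())) for v in range(N)}
    if len(degrees) != 1:
        raise ValueError(f"graph in {path} is not regular: degrees {sorted(degrees)}")
    k = degrees.pop()
    g = _from_neighbor_sets([nbrs_map[v] for v in range(N)], k, family)
    problems = regularity_diagnostics(g)
    if problems:
        raise ValueError(f"invalid graph in {path}: " + "; ".join(problems))
    return g
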