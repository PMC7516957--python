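"""Maximal clique enumeration: pivoting under a degeneracy ordering.

The enumerator follows the standard scheme: an outer loop over a degeneracy
ordering (repeated minimum-degree removal, ties to the smallest vertex id)
restricts each recursion to a vertex's later neighbours; the inner recursion
uses pivoting on the vertex of P ∪ X with the most candidates in P (ties to
the smallest id).  Output is canonical: each clique as a sorted id list, the
list of cliques sorted lexicographically.  Singletons and pairs are reported
too — size filtering is a consumer concern.

``brute_force_maximal_cliques`` is the independent oracle: a definition-level
subset scan with no pivoting and no shared code path.
"""

from __future__ import annotations

import heapq
from typing import Iterable, Sequence

from .errors import GraphSizeError

Clique = tuple[int, ...]


class Graph:
    """Simple undirected graph on vertices 0..n-1 with set adjacency."""

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] = ()) -> None:
        if n < 0:
            raise ValueError("vertex count must be >= 0")
        self._n = n
        self._adj: list[set[int]] = [set() for _ in range(n)]
        for u, v in edges:
            self.add_edge(u, v)

    @property
    def n(self) -> int:
        return self._n

    @property
    def adjacency(self) -> list[set[int]]:
        return self._adj

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-loop on vertex {u}")
        if not (0 <= u < self._n and 0 <= v < self._n):
            raise ValueError(f"edge ({u},{v}) out of range for n={self._n}")
        self._adj[u].add(v)
        self._adj[v].add(u)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in range(self._n) for v in self._adj[u] if u < v
        )

    def n_edges(self) -> int:
        return sum(len(a) for a in self._adj) // 2


def degeneracy_order(graph: Graph) -> tuple[list[int], int]:
    """Vertex ordering by repeated minimum-degree removal, plus degeneracy.

    Each vertex has at most ``degeneracy`` neighbours later in the order.
    Ties are broken by smallest vertex id, making the order deterministic.
    """
    n = graph.n
    adj = graph.adjacency
    degree = [len(adj[v]) for v in range(n)]
    removed = [False] * n
    heap = [(degree[v], v) for v in range(n)]
    heapq.heapify(heap)
    order: list[int] = []
    degeneracy = 0
    while heap:
        dv, v = heapq.heappop(heap)
        if removed[v] or dv != degree[v]:
            continue  # stale entry
        removed[v] = True
        order.append(v)
        degeneracy = max(degeneracy, dv)
        for u in adj[v]:
            if not removed[u]:
                degree[u] -= 1
                heapq.heappush(heap, (degree[u], u))
    return order, degeneracy


def _expand(
    R: list[int],
    P: set[int],
    X: set[int],
    adj: list[set[int]],
    out: list[Clique],
) -> None:
    if not P and not X:
        out.append(tuple(sorted(R)))
        return
    # Pivot: vertex of P ∪ X maximizing |P ∩ N(u)|; iteration over the sorted
    # union makes the smallest id win ties.
    pivot = max(sorted(P | X), key=lambda u: len(P & adj[u]))
    for v in sorted(P - adj[pivot]):
        R.append(v)
        _expand(R, P & adj[v], X & adj[v], adj, out)
        R.pop()
        P.remove(v)
        X.add(v)


def maximal_cliques(graph: Graph) -> list[Clique]:
    """All maximal cliques, each exactly once, canonically ordered."""
    adj = graph.adjacency
    order, _ = degeneracy_order(graph)
    rank = {v: i for i, v in enumerate(order)}
    out: list[Clique] = []
    for v in order:
        later = {u for u in adj[v] if rank[u] > rank[v]}
        earlier = {u for u in adj[v] if rank[u] < rank[v]}
        _expand([v], later, earlier, adj, out)
    out.sort()
    return out


def _bitmask_adjacency(graph: Graph) -> list[int]:
    masks = [0] * graph.n
    for u in range(graph.n):
        for v in graph.adjacency[u]:
            masks[u] |= 1 << v
    return masks


def _scan_all_subsets(graph: Graph) -> list[Clique]:
    # Dynamic subset scan: S (lowest bit v removed → T) is a clique iff T is a
    # clique and v is adjacent to all of T.  Visits every one of the 2^n
    # subsets — the definition-level oracle.
    n = graph.n
    masks = _bitmask_adjacency(graph)
    is_clique = bytearray(1 << n)
    is_clique[0] = 1
    cliques: list[int] = []
    for S in range(1, 1 << n):
        v = (S & -S).bit_length() - 1
        T = S & (S - 1)
        if is_clique[T] and (masks[v] & T) == T:
            is_clique[S] = 1
            cliques.append(S)
    full = (1 << n) - 1
    out: list[Clique] = []
    for S in cliques:
        rest = full & ~S
        maximal = True
        while rest:
            u = (rest & -rest).bit_length() - 1
            if (masks[u] & S) == S:
                maximal = False
                break
            rest &= rest - 1
        if maximal:
            out.append(tuple(i for i in range(n) if S >> i & 1))
    out.sort()
    return out


def _scan_neighbourhoods(graph: Graph, limit: int) -> list[Clique]:
    # Every maximal clique lies inside the closed neighbourhood of each of its
    # members; exhaustively scan subsets of each N[v] instead of all of V.
    n = graph.n
    adj = graph.adjacency
    masks = _bitmask_adjacency(graph)
    found: set[int] = set()
    for v in range(n):
        nb = sorted(adj[v])
        if len(nb) + 1 > limit:
            raise GraphSizeError(
                f"closed neighbourhood of vertex {v} has {len(nb) + 1} vertices"
                f" (limit {limit})"
            )
        m = len(nb)
        for sub in range(1 << m):
            S = 1 << v
            for i in range(m):
                if sub >> i & 1:
                    S |= 1 << nb[i]
            # pairwise adjacency check straight from the definition
            ok = True
            rest = S
            while rest:
                u = (rest & -rest).bit_length() - 1
                if (masks[u] & S) != S & ~(1 << u):
                    ok = False
                    break
                rest &= rest - 1
            if ok:
                found.add(S)
    out: list[Clique] = []
    for S in found:
        maximal = True
        for u in range(n):
            if not (S >> u & 1) and (masks[u] & S) == S:
                maximal = False
                break
        if maximal:
            out.append(tuple(i for i in range(n) if S >> i & 1))
    out.sort()
    return out


def brute_force_maximal_cliques(graph: Graph, limit: int = 20) -> list[Clique]:
    """Exhaustive oracle enumeration (no pivoting, no shared code path).

    For graphs with at most ``limit`` vertices every subset of V is scanned;
    for larger graphs every subset of each closed neighbourhood is scanned
    instead (still exhaustive, since a maximal clique is contained in the
    closed neighbourhood of each member), provided all closed neighbourhoods
    fit within ``limit + 2`` vertices.

    Raises
    ------
    GraphSizeError
        The graph is too large for either scan.
    """
    if graph.n <= limit:
        return _scan_all_subsets(graph)
    return _scan_neighbourhoods(graph, limit + 2)


def check_clique(graph: Graph, members: Sequence[int]) -> bool:
    """Independent pairwise-adjacency check of a vertex set."""
    ms = list(members)
    return all(
        ms[j] in graph.adjacency[ms[i]]
        for i in range(len(ms))
        for j in range(i + 1, len(ms))
    )


def check_maximal(graph: Graph, members: Sequence[int]) -> bool:
    """Independent maximality check: no outside vertex adjacent to all members."""
    s = set(members)
    if not check_clique(graph, members):
        return False
    return not any(
        s <= graph.adjacency[u] for u in range(graph.n) if u not in s
    )
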