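"""Exact maximum-clique search and maximum-clique enumeration.

Two-phase strategy: a Carraghan–Pardalos-style branch-and-bound with a
greedy-colouring upper bound establishes the maximum clique size, then a
pivoted Bron–Kerbosch enumeration, pruned to that size, lists every maximum
clique exactly once.  This is the deterministic baseline and the correctness
oracle for the sampling-based enumerator.

Work is bounded in explored search-tree nodes (not wall clock) so that limit
behaviour is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


class CliqueWorkLimitError(Exception):
    """Raised when the configured search-node budget is exhausted."""

    def __init__(self, explored: int, best_so_far: int):
        super().__init__(f"clique search exceeded work limit after {explored} nodes")
        self.explored = explored
        self.best_so_far = best_so_far


@dataclass(frozen=True)
class Clique:
    vertex_ids: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.vertex_ids)

    def sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.vertex_ids))


@dataclass
class CliqueEnumeration:
    cliques: list[Clique]  # canonical order: sorted vertex tuples
    max_size: int

    @property
    def m(self) -> int:
        return len(self.cliques)

    def as_sets(self) -> set[frozenset[int]]:
        return {c.vertex_ids for c in self.cliques}


def _as_adjacency(graph) -> np.ndarray:
    """Accept a ModularProduct, a boolean matrix, or a networkx graph."""
    adj = getattr(graph, "adjacency", graph)
    if not isinstance(adj, np.ndarray):
        import networkx as nx

        if isinstance(graph, nx.Graph):
            nodes = sorted(graph.nodes())
            if nodes != list(range(len(nodes))):
                raise ValueError("graph nodes must be 0..N-1")
            adj = nx.to_numpy_array(graph, nodelist=nodes, dtype=bool)
        else:
            adj = np.asarray(adj, dtype=bool)
    adj = adj.astype(bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    return adj


def _neighbor_sets(adj: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(adj[v]).tolist()) for v in range(adj.shape[0])]


def _greedy_color_bound(candidates: list[int], nbrs: list[set[int]]) -> list[tuple[int, int]]:
    """Greedy colouring of the candidate set; returns (vertex, colour) pairs
    in colouring order.  The colour number is an upper bound on the largest
    clique inside the candidates containing that vertex and its successors."""
    color_classes: list[set[int]] = []
    order: list[tuple[int, int]] = []
    for v in candidates:
        for c, cls in enumerate(color_classes):
            if not (nbrs[v] & cls):
                cls.add(v)
                order.append((v, c + 1))
                break
        else:
            color_classes.append({v})
            order.append((v, len(color_classes)))
    order.sort(key=lambda vc: vc[1])
    return order


def max_clique_size(graph, work_limit: int | None = None) -> int:
    """Size of the largest clique (0 for the empty graph)."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n == 0:
        return 0
    nbrs = _neighbor_sets(adj)
    best = 0
    explored = 0

    # expand candidates in degeneracy-ish order: ascending degree
    initial = sorted(range(n), key=lambda v: len(nbrs[v]))

    def expand(current_size: int, candidates: list[int]) -> None:
        nonlocal best, explored
        explored += 1
        if work_limit is not None and explored > work_limit:
            raise CliqueWorkLimitError(explored, best)
        colored = _greedy_color_bound(candidates, nbrs)
        # iterate highest colour first for tighter pruning
        for idx in range(len(colored) - 1, -1, -1):
            v, color = colored[idx]
            if current_size + color <= best:
                return
            new_candidates = [u for u, _ in colored[:idx] if u in nbrs[v]]
            if current_size + 1 > best:
                best = current_size + 1
            if new_candidates:
                expand(current_size + 1, new_candidates)

    expand(0, initial)
    return best


def enumerate_max_cliques(
    graph, work_limit: int | None = None, target_size: int | None = None
) -> CliqueEnumeration:
    """Enumerate ALL maximum cliques, each exactly once.

    Pivoted Bron–Kerbosch restricted to branches that can still reach the
    maximum size; every maximum clique is maximal, so none is missed.
    """
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n == 0:
        return CliqueEnumeration([], 0)
    k = target_size if target_size is not None else max_clique_size(adj, work_limit)
    if k == 0:
        return CliqueEnumeration([], 0)
    nbrs = _neighbor_sets(adj)
    found: list[frozenset[int]] = []
    explored = 0

    def bk(r: set[int], p: set[int], x: set[int]) -> None:
        nonlocal explored
        explored += 1
        if work_limit is not None and explored > work_limit:
            raise CliqueWorkLimitError(explored, k)
        if not p and not x:
            if len(r) == k:
                found.append(frozenset(r))
            return
        if len(r) + len(p) < k:
            return
        # Tomita pivot: vertex of P ∪ X maximising |P ∩ N(u)|
        pivot = max(p | x, key=lambda u: len(p & nbrs[u]))
        for v in list(p - nbrs[pivot]):
            bk(r | {v}, p & nbrs[v], x & nbrs[v])
            p.remove(v)
            x.add(v)

    bk(set(), set(range(n)), set())
    cliques = [Clique(c) for c in sorted(found, key=lambda c: tuple(sorted(c)))]
    return CliqueEnumeration(cliques, k)


def enumerate_cliques_of_size(graph, k: int) -> list[Clique]:
    """ALL cliques of exactly size k, maximal or not, each exactly once.

    Needed when every maximum clique is chemically unrealisable (the
    triangle-vs-star pathology): the best realisable bond correspondence may
    be a non-maximal clique one size down.
    """
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if k <= 0 or n == 0:
        return []
    nbrs = _neighbor_sets(adj)
    out: list[frozenset[int]] = []

    def extend(r: list[int], cand: list[int]) -> None:
        if len(r) == k:
            out.append(frozenset(r))
            return
        for idx, v in enumerate(cand):
            if len(r) + len(cand) - idx < k:
                return
            extend(r + [v], [u for u in cand[idx + 1 :] if u in nbrs[v]])

    extend([], list(range(n)))
    return [Clique(c) for c in sorted(out, key=lambda c: tuple(sorted(c)))]


def brute_force_max_cliques(graph) -> CliqueEnumeration:
    """Independent oracle: exhaustive subset search (N <= ~20 only)."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n > 22:
        raise ValueError("brute force limited to N <= 22")
    best: list[frozenset[int]] = []
    best_k = 0
    for mask in range(1 << n):
        members = [v for v in range(n) if mask >> v & 1]
        if len(members) < best_k:
            continue
        ok = all(adj[u, v] for i, u in enumerate(members) for v in members[i + 1 :])
        if ok:
            if len(members) > best_k:
                best_k = len(members)
                best = []
            best.append(frozenset(members))
    if best_k == 0:
        return CliqueEnumeration([], 0)
    return CliqueEnumeration(
        [Clique(c) for c in sorted(best, key=lambda c: tuple(sorted(c)))], best_k
    )
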