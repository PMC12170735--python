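"""Ground-truth search: temporal DFS, path enumeration, rainbow-path check.

These are exponential-time reference implementations used to validate the
algebraic oracle on small instances (and available as a CLI engine for tiny
graphs).  No memoization is attempted: for *simple* paths the admissible
continuations depend on the whole visited set, so caching by (vertex, time)
would be unsound.  Explicit size guards keep the exhaustive searches at desk
scale.
"""

from __future__ import annotations

from .temporal_graph import (
    ColorMultiset,
    RestingTimes,
    RestlessPathWitness,
    StaticExpansion,
    TemporalGraph,
    VertexColoring,
)

__all__ = [
    "dfs_reach",
    "enumerate_restless_paths",
    "brute_reach_cells",
    "rainbow_path_exists",
]

_ENUM_GUARD = 10**7


def _max_out_degree(g: TemporalGraph) -> int:
    deg: dict[int, int] = {}
    for u, _, _ in g.edges:
        deg[u] = deg.get(u, 0) + 1
    return max(deg.values(), default=0)


def _check_guard(g: TemporalGraph, k: int) -> None:
    if _max_out_degree(g) ** max(k, 1) > _ENUM_GUARD:
        raise ValueError(
            f"instance too large for exhaustive enumeration "
            f"(d_max^k = {_max_out_degree(g)}^{k} exceeds {_ENUM_GUARD})"
        )


def _dfs_paths(g: TemporalGraph, delta: RestingTimes, s: int, max_edges: int):
    """Yield (vertices, times) for every simple restless path from s.

    Paths of 1..max_edges edges are yielded as they are discovered.  The
    start vertex departs at any timestamp; at internal vertices the waiting
    gap between arrival and departure is bounded by the resting time.
    """
    out_by_vertex: dict[int, list[tuple[int, int]]] = {}
    for u, v, t in g.edges:
        out_by_vertex.setdefault(u, []).append((v, t))

    path_v = [s]
    path_t: list[int] = []
    visited = {s}

    def extend():
        v = path_v[-1]
        depth = len(path_t)
        if depth == max_edges:
            return
        arrival = path_t[-1] if path_t else None
        for w, t in out_by_vertex.get(v, ()):
            if w in visited:
                continue
            if arrival is not None and (t < arrival or t - arrival > delta[v]):
                continue
            path_v.append(w)
            path_t.append(t)
            visited.add(w)
            yield (tuple(path_v), tuple(path_t))
            yield from extend()
            visited.discard(w)
            path_v.pop()
            path_t.pop()

    yield from extend()


def dfs_reach(
    g: TemporalGraph, delta: RestingTimes, s: int, k: int
) -> dict[tuple[int, int], int]:
    """Exhaustive temporal DFS: earliest arrival per (vertex, path length).

    Returns a map ``(vertex, length) -> earliest last-edge timestamp`` over
    all simple restless paths from ``s`` with ``1..k-1`` edges.  Worst-case
    cost ``O(d_max^k)``.
    """
    if k < 2:
        raise ValueError("k must be at least 2 (paths with at least one edge)")
    best: dict[tuple[int, int], int] = {}
    for verts, times in _dfs_paths(g, delta, s, k - 1):
        key = (verts[-1], len(times))
        t = times[-1]
        if key not in best or t < best[key]:
            best[key] = t
    return best


def enumerate_restless_paths(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    k: int,
    d: int | None = None,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
) -> list[RestlessPathWitness]:
    """All simple restless paths with exactly ``k`` vertices starting at ``s``.

    Optionally restricted to destination ``d`` and/or filtered to paths whose
    vertex-color multiset equals ``motif``.  ``k = 1`` returns the single
    zero-length path ``(s)``.  Refuses instances beyond the ``d_max^k`` guard.
    """
    if k < 1:
        raise ValueError("k must be positive")
    _check_guard(g, k)
    if motif is not None and coloring is None:
        raise ValueError("a color multiset requires a coloring")

    def admit(verts: tuple[int, ...]) -> bool:
        if motif is not None and coloring is not None:
            found = ColorMultiset.from_iterable(coloring[v] for v in verts)
            if found.mu != dict(motif.mu):
                return False
        return True

    out: list[RestlessPathWitness] = []
    if k == 1:
        if (d is None or d == s) and admit((s,)):
            out.append(RestlessPathWitness((s,), ()))
        return out
    for verts, times in _dfs_paths(g, delta, s, k - 1):
        if len(times) != k - 1:
            continue
        if d is not None and verts[-1] != d:
            continue
        if admit(verts):
            out.append(RestlessPathWitness(verts, times))
    return out


def brute_reach_cells(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    ell: int,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
    tau_limit: int | None = None,
) -> set[tuple[int, int]]:
    """Ground-truth fine-grained table for paths with exactly ``ell`` vertices.

    Returns the set of cells ``(vertex, last-edge time)`` realized by some
    simple restless path from ``s`` (optionally motif-filtered, optionally
    with last-edge time capped at ``tau_limit``).
    """
    limit = g.tau if tau_limit is None else tau_limit
    cells = {
        (w.vertices[-1], w.times[-1])
        for w in enumerate_restless_paths(g, delta, s, ell, coloring=coloring, motif=motif)
        if w.times and w.times[-1] <= limit
    }
    return cells


def rainbow_path_exists(
    expansion: StaticExpansion,
    src_nodes: set[tuple[int, int]],
    dst_nodes: set[tuple[int, int]],
    node_guard: int = 5000,
) -> bool:
    """Brute-force rainbow-path search on a time-expanded digraph.

    A rainbow path repeats no node color; colors here are original vertex
    ids, so a source-to-destination rainbow path in the expansion mirrors a
    restless path in the temporal graph.  DFS without memoization, guarded
    by the expansion size.
    """
    if len(expansion.nodes) > node_guard:
        raise ValueError(
            f"expansion too large for brute-force rainbow search "
            f"({len(expansion.nodes)} > {node_guard} nodes)"
        )
    out_arcs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in expansion.arcs:
        out_arcs.setdefault(a, []).append(b)

    dst = {v for v in dst_nodes if v in expansion.nodes}
    if not dst:
        return False

    def dfs(node: tuple[int, int], used: set[int]) -> bool:
        if node in dst:
            return True
        for nxt in out_arcs.get(node, ()):
            c = StaticExpansion.node_color(nxt)
            if c in used:
                continue
            used.add(c)
            if dfs(nxt, used):
                return True
            used.discard(c)
        return False

    for start in sorted(src_nodes):
        if start not in expansion.nodes:
            continue
        if dfs(start, {StaticExpansion.node_color(start)}):
            return True
    return False
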