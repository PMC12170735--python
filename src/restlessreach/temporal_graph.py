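"""Temporal-graph data model, edge-list I/O, expansion and pruning.

A temporal graph is a set of directed, timestamped contacts ``(u, v, t)``
over vertices ``1..n`` with integer timestamps in ``[1, tau]``.  An edge can
be traversed only at its own timestamp, and a diffusion process waiting at a
vertex ``v`` stays viable for at most ``delta(v)`` time steps — the resting
(waiting) time, the SIR-recovery analogue that motivates *restless* paths:
time-respecting paths whose waiting gap at every internal vertex is bounded
by that vertex's resting time.

Conventions used throughout the package:

* vertices and timestamps are 1-based; waiting windows are inclusive
  ``{0, ..., delta(v)}``;
* the waiting bound binds at internal vertices only — a path may depart from
  its start vertex at any timestamp;
* self-loops are rejected (a path can never use one) and exact duplicate
  triples are dropped at construction (their count is reported).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TemporalGraph",
    "RestingTimes",
    "VertexColoring",
    "ColorMultiset",
    "StaticExpansion",
    "RestlessPathWitness",
    "PrunedGraph",
    "tel_read",
    "tel_write",
    "read_resting_tsv",
    "read_coloring_tsv",
    "delta_expansion",
    "preprocess_prune",
    "temporal_degree",
    "five_vertex_example",
]


class TemporalGraph:
    """Directed temporal graph with per-timestamp adjacency.

    Parameters
    ----------
    n:
        Number of vertices; vertex ids are ``1..n``.
    edges:
        Iterable of ``(u, v, t)`` triples.  Exact duplicates are dropped
        (count in :attr:`duplicates_dropped`); self-loops raise.
    tau:
        Maximum timestamp.  Defaults to the largest edge timestamp
        (or 1 for an edgeless graph).
    """

    def __init__(self, n: int, edges: Iterable[tuple[int, int, int]], tau: int | None = None):
        if n < 0:
            raise ValueError("vertex count must be non-negative")
        seen: dict[tuple[int, int, int], None] = {}
        dropped = 0
        for u, v, t in edges:
            if not (1 <= u <= n and 1 <= v <= n):
                raise ValueError(f"edge ({u},{v},{t}): vertex id out of range [1,{n}]")
            if u == v:
                raise ValueError(f"edge ({u},{v},{t}): self-loops are not allowed")
            if t < 1:
                raise ValueError(f"edge ({u},{v},{t}): timestamps are 1-based")
            if (u, v, t) in seen:
                dropped += 1
            else:
                seen[(u, v, t)] = None
        self.n = n
        self.edges: tuple[tuple[int, int, int], ...] = tuple(seen)
        self.duplicates_dropped = dropped
        max_t = max((t for _, _, t in self.edges), default=1)
        self.tau = int(tau) if tau is not None else max_t
        if max_t > self.tau:
            raise ValueError(f"edge timestamp {max_t} exceeds tau={self.tau}")
        # per-timestamp adjacency: (vertex, time) -> [(neighbor, edge index)]
        self._in: dict[tuple[int, int], list[tuple[int, int]]] = {}
        self._out: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for idx, (u, v, t) in enumerate(self.edges):
            self._out.setdefault((u, t), []).append((v, idx))
            self._in.setdefault((v, t), []).append((u, idx))

    @property
    def m(self) -> int:
        return len(self.edges)

    def in_at(self, v: int, t: int) -> list[tuple[int, int]]:
        """In-neighbors of ``v`` via edges with timestamp ``t``, as (u, edge-id)."""
        return self._in.get((v, t), [])

    def out_at(self, u: int, t: int) -> list[tuple[int, int]]:
        return self._out.get((u, t), [])

    def out_times(self, u: int) -> list[int]:
        """Sorted distinct departure timestamps of ``u``."""
        return sorted({t for (uu, t) in self._out if uu == u})

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edges as parallel int64 arrays (src, dst, time) for the kernels."""
        if self.m == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        arr = np.asarray(self.edges, dtype=np.int64)
        return arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy()

    def remove_vertices(self, vs: Iterable[int]) -> "TemporalGraph":
        """Same vertex universe, with all edges incident to ``vs`` deleted."""
        drop = set(vs)
        kept = [e for e in self.edges if e[0] not in drop and e[1] not in drop]
        return TemporalGraph(self.n, kept, tau=self.tau)

    def remove_in_edges(self, v: int) -> "TemporalGraph":
        kept = [e for e in self.edges if e[1] != v]
        return TemporalGraph(self.n, kept, tau=self.tau)

    def static_digraph(self) -> nx.DiGraph:
        """Merged static digraph: arc (u, v) iff some temporal (u, v, t) exists."""
        g = nx.DiGraph()
        g.add_nodes_from(range(1, self.n + 1))
        g.add_edges_from({(u, v) for u, v, _ in self.edges})
        return g

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TemporalGraph)
            and self.n == other.n
            and self.tau == other.tau
            and set(self.edges) == set(other.edges)
        )

    def __repr__(self) -> str:
        return f"TemporalGraph(n={self.n}, m={self.m}, tau={self.tau})"


@dataclass(frozen=True)
class RestingTimes:
    """Per-vertex resting (waiting) times; ``delta[v]`` indexed 1-based."""

    delta: tuple[int, ...]  # length n + 1, entry 0 unused

    @staticmethod
    def constant(n: int, value: int) -> "RestingTimes":
        return RestingTimes((0,) + (int(value),) * n)

    @staticmethod
    def from_map(n: int, values: Mapping[int, int] | Sequence[int]) -> "RestingTimes":
        if isinstance(values, Mapping):
            d = [0] + [int(values[v]) for v in range(1, n + 1)]
        else:
            if len(values) != n:
                raise ValueError("resting-time vector length must equal n")
            d = [0] + [int(x) for x in values]
        if any(x < 0 for x in d):
            raise ValueError("resting times must be non-negative")
        return RestingTimes(tuple(d))

    def __getitem__(self, v: int) -> int:
        return self.delta[v]

    @property
    def n(self) -> int:
        return len(self.delta) - 1

    @property
    def Delta(self) -> int:
        """Maximum resting time over all vertices."""
        return max(self.delta[1:], default=0)

    def with_source_unbounded(self, s: int, tau: int) -> "RestingTimes":
        """Copy with ``delta(s) = tau`` (the conventional source exemption)."""
        d = list(self.delta)
        d[s] = tau
        return RestingTimes(tuple(d))


@dataclass(frozen=True)
class VertexColoring:
    """Single color per vertex, colors in ``1..num_colors``; 1-based vector."""

    color: tuple[int, ...]  # length n + 1, entry 0 unused
    num_colors: int

    @staticmethod
    def from_list(colors: Sequence[int], num_colors: int | None = None) -> "VertexColoring":
        cs = tuple(int(c) for c in colors)
        nc = int(num_colors) if num_colors is not None else max(cs, default=1)
        if any(not (1 <= c <= nc) for c in cs):
            raise ValueError("vertex colors must lie in [1, num_colors]")
        return VertexColoring((0,) + cs, nc)

    @staticmethod
    def unit(n: int) -> "VertexColoring":
        return VertexColoring((0,) + (1,) * n, 1)

    def __getitem__(self, v: int) -> int:
        return self.color[v]

    @property
    def n(self) -> int:
        return len(self.color) - 1


@dataclass(frozen=True)
class ColorMultiset:
    """Multiset of path-vertex colors; ``mu[color]`` is the multiplicity."""

    mu: Mapping[int, int]

    def __post_init__(self):
        if any(m < 1 for m in self.mu.values()):
            raise ValueError("zero-multiplicity colors must be absent from the map")

    @staticmethod
    def from_iterable(colors: Iterable[int]) -> "ColorMultiset":
        mu: dict[int, int] = {}
        for c in colors:
            mu[c] = mu.get(c, 0) + 1
        return ColorMultiset(mu)

    @property
    def k(self) -> int:
        """Total size (= number of path vertices it constrains)."""
        return sum(self.mu.values())

    def count(self, color: int) -> int:
        return self.mu.get(color, 0)

    def add(self, color: int, times: int = 1) -> "ColorMultiset":
        mu = dict(self.mu)
        mu[color] = mu.get(color, 0) + times
        return ColorMultiset(mu)

    def remove_one(self, color: int) -> "ColorMultiset":
        if self.count(color) < 1:
            raise ValueError(f"color {color} absent from multiset")
        mu = dict(self.mu)
        mu[color] -= 1
        if mu[color] == 0:
            del mu[color]
        return ColorMultiset(mu)

    def as_sorted_tuple(self) -> tuple[int, ...]:
        out: list[int] = []
        for c in sorted(self.mu):
            out.extend([c] * self.mu[c])
        return tuple(out)


@dataclass(frozen=True)
class StaticExpansion:
    """Time-expanded static digraph realizing admissible waits.

    Nodes are (vertex, time) pairs; an arc ((v_i, t), (v_j, t')) exists iff
    (v_i, v_j, t) is a temporal edge and 0 <= t' - t <= delta(v_j) with
    t' <= tau.  Each node is colored by its original vertex id, so restless
    paths of the temporal graph correspond to rainbow paths here.
    """

    nodes: frozenset[tuple[int, int]]
    arcs: frozenset[tuple[tuple[int, int], tuple[int, int]]]

    @staticmethod
    def node_color(node: tuple[int, int]) -> int:
        return node[0]


@dataclass(frozen=True)
class RestlessPathWitness:
    """A certified restless path: vertices ``v_1..v_k``, edge times ``t_1..t_{k-1}``."""

    vertices: tuple[int, ...]
    times: tuple[int, ...]

    def __post_init__(self):
        if len(self.times) != max(len(self.vertices) - 1, 0):
            raise ValueError("witness needs exactly one timestamp per edge")

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.times)

    @property
    def max_time(self) -> int:
        return max(self.times) if self.times else 0

    def to_tsv(self) -> str:
        lines = ["step\tvertex\ttime"]
        for i, v in enumerate(self.vertices):
            t = "" if i == 0 else str(self.times[i - 1])
            lines.append(f"{i + 1}\t{v}\t{t}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# edge-list I/O (.tel): header "n m tau", one "u v t" triple per data line
# ---------------------------------------------------------------------------

def tel_read(path_or_file, undirected: bool = False) -> tuple[TemporalGraph, dict]:
    """Read a plain-text temporal edge list.

    The first non-comment line is the header ``n m tau``; the following ``m``
    data lines each hold one ``u v t`` triple.  Lines starting with ``#`` are
    ignored.  With ``undirected=True`` every line yields two opposing
    directed edges.
    """
    if hasattr(path_or_file, "read"):
        lines = path_or_file.read().splitlines()
        name = getattr(path_or_file, "name", "<stream>")
    else:
        name = str(path_or_file)
        with open(path_or_file, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    header = None
    triples: list[tuple[int, int, int]] = []
    data_lines = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{name}:{lineno}: expected three integers, got {raw!r}")
        try:
            a, b, c = (int(x) for x in parts)
        except ValueError as exc:
            raise ValueError(f"{name}:{lineno}: non-integer token in {raw!r}") from exc
        if header is None:
            header = (a, b, c)
            continue
        data_lines += 1
        n, _, tau = header
        if not (1 <= a <= n and 1 <= b <= n):
            raise ValueError(f"{name}:{lineno}: vertex id out of range [1,{n}]")
        if not (1 <= c <= tau):
            raise ValueError(f"{name}:{lineno}: timestamp out of range [1,{tau}]")
        triples.append((a, b, c))
        if undirected:
            triples.append((b, a, c))
    if header is None:
        raise ValueError(f"{name}: missing header line 'n m tau'")
    n, m, tau = header
    if data_lines != m:
        raise ValueError(f"{name}: header declares m={m} edges but found {data_lines}")
    g = TemporalGraph(n, triples, tau=tau)
    meta = {"duplicates_dropped": g.duplicates_dropped, "undirected": undirected}
    return g, meta


def tel_write(g: TemporalGraph, path_or_file) -> None:
    """Write a temporal graph so that :func:`tel_read` reproduces its edge set."""
    buf = io.StringIO()
    buf.write(f"{g.n} {g.m} {g.tau}\n")
    for u, v, t in g.edges:
        buf.write(f"{u} {v} {t}\n")
    text = buf.getvalue()
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w", encoding="utf-8") as fh:
            fh.write(text)


def _read_two_column(path_or_file, what: str) -> dict[int, int]:
    if hasattr(path_or_file, "read"):
        lines = path_or_file.read().splitlines()
    else:
        with open(path_or_file, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    out: dict[int, int] = {}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#") or line.split()[0] == "vertex":
            continue
        v, x = line.split()
        out[int(v)] = int(x)
    if not out:
        raise ValueError(f"empty {what} file")
    return out


def read_resting_tsv(path_or_file, n: int) -> RestingTimes:
    """Companion TSV ``vertex delta`` -> :class:`RestingTimes`."""
    return RestingTimes.from_map(n, _read_two_column(path_or_file, "resting-time"))


def read_coloring_tsv(path_or_file, n: int) -> VertexColoring:
    """Companion TSV ``vertex color`` -> :class:`VertexColoring`."""
    vals = _read_two_column(path_or_file, "coloring")
    return VertexColoring.from_list([vals[v] for v in range(1, n + 1)])


# ---------------------------------------------------------------------------
# expansion, pruning, degrees
# ---------------------------------------------------------------------------

def delta_expansion(g: TemporalGraph, delta: RestingTimes) -> StaticExpansion:
    """Static time-expanded digraph of ``g`` under resting times ``delta``.

    The arc count is at most ``(Delta + 1) * m``, with equality exactly when
    no arc is clipped by the ``t + l <= tau`` horizon.  Node set = arc
    endpoints (an isolated timestamp copy carries no information).
    """
    arcs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for u, v, t in g.edges:
        for lag in range(delta[v] + 1):
            tp = t + lag
            if tp > g.tau:
                break
            arcs.add(((u, t), (v, tp)))
    nodes = {a for a, _ in arcs} | {b for _, b in arcs}
    return StaticExpansion(nodes=frozenset(nodes), arcs=frozenset(arcs))


@dataclass(frozen=True)
class PrunedGraph:
    """Pruning result: subgraph re-labelled ``1..n'`` plus the id maps."""

    graph: TemporalGraph
    kept: tuple[int, ...]          # new id i (1-based) -> original id kept[i-1]
    old_to_new: Mapping[int, int]

    def original_id(self, new_id: int) -> int:
        return self.kept[new_id - 1]


def preprocess_prune(
    g: TemporalGraph,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
    source: int | None = None,
) -> PrunedGraph:
    """Heuristic instance shrinking that provably preserves reachability answers.

    Two reductions: (i) with a color query, vertices whose color has zero
    multiplicity in the multiset can never lie on a properly colored path and
    are removed with their edges; (ii) with a source, vertices unreachable
    from it in the merged static digraph are removed (a restless path implies
    a static path; the converse need not hold, so this only deletes provably
    unreachable vertices).
    """
    if motif is not None and coloring is None:
        raise ValueError("a color multiset requires a coloring")
    alive = set(range(1, g.n + 1))
    if motif is not None and coloring is not None:
        alive = {v for v in alive if motif.count(coloring[v]) > 0}
    if source is not None:
        if source not in alive:
            raise ValueError(f"source {source} was pruned away (color not in multiset)")
        sub = [e for e in g.edges if e[0] in alive and e[1] in alive]
        static = nx.DiGraph()
        static.add_nodes_from(alive)
        static.add_edges_from({(u, v) for u, v, _ in sub})
        reach = {source} | nx.descendants(static, source)
        alive &= reach
    kept = tuple(sorted(alive))
    old_to_new = {old: i + 1 for i, old in enumerate(kept)}
    edges = [
        (old_to_new[u], old_to_new[v], t)
        for u, v, t in g.edges
        if u in alive and v in alive
    ]
    return PrunedGraph(
        graph=TemporalGraph(len(kept), edges, tau=g.tau),
        kept=kept,
        old_to_new=old_to_new,
    )


def temporal_degree(g: TemporalGraph, v: int) -> int:
    """Number of temporal edges incident to ``v`` (in + out)."""
    if not (1 <= v <= g.n):
        raise ValueError(f"vertex {v} out of range [1,{g.n}]")
    return sum(1 for u, w, _ in g.edges if u == v or w == v)


def five_vertex_example() -> tuple[TemporalGraph, RestingTimes]:
    """The five-vertex documentation instance used throughout docs and tests.

    A directed temporal graph on vertices ``v1..v5`` with edges
    ``(1,2,1), (2,3,2), (3,4,3), (4,2,4), (2,5,5)``, horizon ``tau = 5`` and
    constant resting time 2.  It is small enough to enumerate by hand yet
    rich enough to separate walks from paths: the only length-5 restless walk
    into ``v5`` revisits ``v2``, so ``v5`` is walk-reachable but not
    path-reachable from ``v1``.
    """
    g = TemporalGraph(5, [(1, 2, 1), (2, 3, 2), (3, 4, 3), (4, 2, 4), (2, 5, 5)], tau=5)
    return g, RestingTimes.constant(5, 2)
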