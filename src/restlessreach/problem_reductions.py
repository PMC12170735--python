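"""Reachability problems solved by constructions around the fine-grained oracle.

Each named problem is reduced to one or more constrained-sieve queries:

* exact-length reachability from a source — recolor the source with a
  private color, delete its in-edges, and query with the multiset
  ``{1^(k-1), 2}``;
* motif reachability (color-multiset constrained) — attach a super-source
  with a fresh color whose out-edges mirror the source's departure times,
  and query with the multiset extended by that color;
* at-most-k and full reachability — union the exact-length tables over the
  admissible lengths;
* multi-source variants — a super-source adjacent to every source.

All outputs are per-(vertex, timestamp) tables or summaries derived from
them, inheriting the sieve's one-sided error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .sieve_oracle import ReachabilityTable, SieveOptions, fine_grained_oracle
from .temporal_graph import (
    ColorMultiset,
    RestingTimes,
    TemporalGraph,
    VertexColoring,
)

__all__ = [
    "ReachSummary",
    "k_restless_reach",
    "k_restless_motif_reach",
    "atm_k_restless_reach",
    "restless_reach",
    "multi_source",
    "st_decision",
]


@dataclass
class ReachSummary:
    """Per-vertex reachability summary across path lengths.

    ``min_time[v]`` is the earliest last-edge timestamp over all qualifying
    paths into ``v`` and ``min_length[v]`` the smallest path length (edge
    count) reaching it; vertices absent from both maps were not reached.
    ``tables`` retains the per-length fine-grained tables (keyed by vertex
    count) for callers that need the full (vertex, length, time) relation.
    """

    n: int
    source: int | None
    min_time: dict[int, int]
    min_length: dict[int, int]
    tables: dict[int, ReachabilityTable]

    @property
    def reached(self) -> set[int]:
        return set(self.min_time)

    def to_tsv(self) -> str:
        lines = ["vertex\tmin_time\tmin_length"]
        for v in sorted(self.min_time):
            lines.append(f"{v}\t{self.min_time[v]}\t{self.min_length[v]}")
        return "\n".join(lines) + "\n"


def _clear_rows(table: ReachabilityTable, rows: Iterable[int], n: int) -> ReachabilityTable:
    reach = table.reach[: n + 1].copy()
    for r in rows:
        if r <= n:
            reach[r] = False
    return ReachabilityTable(reach=reach, ell=table.ell, tau_limit=table.tau_limit)


def k_restless_reach(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    k: int,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachabilityTable:
    """Exact-length reachability: paths of exactly ``k - 1`` edges from ``s``.

    Construction: give ``s`` a private color 2 (everyone else 1), delete its
    in-edges so it can only start paths, and query the oracle with the
    multiset ``{1^(k-1), 2}`` at ``ell = k``.  The returned table covers the
    original vertices with the source row cleared.
    """
    if not (1 <= s <= g.n):
        raise ValueError(f"source {s} out of range [1,{g.n}]")
    if not (2 <= k <= g.n):
        raise ValueError(f"k must lie in [2, n]; got {k}")
    colors = [1] * g.n
    colors[s - 1] = 2
    coloring = VertexColoring.from_list(colors, num_colors=2)
    motif = ColorMultiset({1: k - 1, 2: 1})
    table = fine_grained_oracle(
        g.remove_in_edges(s), coloring, delta, motif, replace(opts, ell=k), engine=engine
    )
    return _clear_rows(table, [s], g.n)


def _with_super_source(
    g: TemporalGraph, sources: Iterable[int], delta: RestingTimes
) -> tuple[TemporalGraph, RestingTimes, int]:
    """Extend the graph by a super-source adjacent to each source.

    The super-source gets one edge to ``s`` at every timestamp where ``s``
    departs, so the zero-wait pairing always exists and extra pairings are
    genuine restless paths.  Its resting time is immaterial (no waiting
    occurs before a start's first edge); it is set to the maximum for
    definiteness.
    """
    sprime = g.n + 1
    edges = list(g.edges)
    for s in sources:
        for t in g.out_times(s):
            edges.append((sprime, s, t))
    g2 = TemporalGraph(sprime, edges, tau=g.tau)
    delta2 = RestingTimes(tuple(delta.delta) + (delta.Delta,))
    return g2, delta2, sprime


def k_restless_motif_reach(
    g: TemporalGraph,
    coloring: VertexColoring,
    delta: RestingTimes,
    s: int,
    motif: ColorMultiset,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachabilityTable:
    """Motif reachability: paths from ``s`` whose vertex colors agree with ``motif``.

    A super-source with a fresh color pins the path origin: it is adjacent
    only to ``s`` (at ``s``'s own departure times), so any properly colored
    path under the extended multiset starts super-source -> s.  Rows for the
    source and super-source are excluded from the result.
    """
    if not (1 <= s <= g.n):
        raise ValueError(f"source {s} out of range [1,{g.n}]")
    k = motif.k
    if k < 1:
        raise ValueError("motif must be non-empty")
    if not g.out_times(s):
        warnings.warn(f"source {s} has no out-edges; nothing is reachable")
        tau = g.tau if opts.tau_limit is None else opts.tau_limit
        return ReachabilityTable(
            reach=np.zeros((g.n + 1, tau + 1), dtype=bool), ell=k + 1, tau_limit=tau
        )
    g2, delta2, sprime = _with_super_source(g, [s], delta)
    fresh = coloring.num_colors + 1
    coloring2 = VertexColoring.from_list(
        list(coloring.color[1:]) + [fresh], num_colors=fresh
    )
    table = fine_grained_oracle(
        g2, coloring2, delta2, motif.add(fresh), replace(opts, ell=k + 1), engine=engine
    )
    return _clear_rows(table, [s, sprime], g.n)


def _summarize(
    n: int, source: int | None, tables: Mapping[int, ReachabilityTable]
) -> ReachSummary:
    min_time: dict[int, int] = {}
    min_length: dict[int, int] = {}
    for ell in sorted(tables):
        table = tables[ell]
        length = ell - 1
        for v in range(1, n + 1):
            t = table.earliest(v)
            if t is None:
                continue
            if v not in min_time or t < min_time[v]:
                min_time[v] = t
            if v not in min_length:
                min_length[v] = length
    return ReachSummary(
        n=n, source=source, min_time=min_time, min_length=min_length, tables=dict(tables)
    )


def atm_k_restless_reach(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    k: int,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachSummary:
    """Reachability by paths of at most ``k - 1`` edges: union over exact lengths."""
    if k < 2:
        raise ValueError("k must be at least 2")
    tables = {
        ell: k_restless_reach(g, delta, s, ell, opts, engine=engine)
        for ell in range(2, min(k, g.n) + 1)
    }
    return _summarize(g.n, s, tables)


def restless_reach(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachSummary:
    """Unbounded-length restless reachability: all lengths up to ``n - 1`` edges."""
    if g.m == 0 or g.n < 2:
        return ReachSummary(n=g.n, source=s, min_time={}, min_length={}, tables={})
    return atm_k_restless_reach(g, delta, s, g.n, opts, engine=engine)


def multi_source(
    g: TemporalGraph,
    delta: RestingTimes,
    sources: Iterable[int],
    opts: SieveOptions,
    k: int | None = None,
    engine: str = "numba",
) -> ReachSummary:
    """Reachability from a set of sources (some member reaches the vertex).

    Reduces to single-source reachability from a super-source adjacent to
    every member; path lengths shift by the extra leading edge, so the
    summary subtracts one and drops the trivial super-source -> member hop.
    """
    S = sorted(set(sources))
    if not S:
        raise ValueError("source set must be non-empty")
    for s in S:
        if not (1 <= s <= g.n):
            raise ValueError(f"source {s} out of range [1,{g.n}]")
    g2, delta2, sprime = _with_super_source(g, S, delta)
    k2 = g2.n if k is None else min(k + 1, g2.n)
    summary2 = atm_k_restless_reach(g2, delta2, sprime, k2, opts, engine=engine)
    # A k'-vertex path from the super-source is a (k'-1)-vertex path from a
    # member; the 2-vertex tables are the artificial hop itself and vanish.
    tables = {
        ell2 - 1: _clear_rows(table, [sprime], g.n)
        for ell2, table in summary2.tables.items()
        if ell2 >= 3
    }
    summary = _summarize(g.n, None, tables)
    return summary


def st_decision(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    d: int,
    opts: SieveOptions,
    k: int | None = None,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
    engine: str = "numba",
) -> tuple[bool, int | None]:
    """Source-to-destination decision: does a qualifying restless path exist?

    With ``motif`` (and ``coloring``): motif-constrained paths; with ``k``:
    exact ``k``-vertex paths; with neither: any length.  Returns the answer
    and the earliest last-edge timestamp when reachable.
    """
    if d == s:
        raise ValueError("destination must differ from the source")
    if motif is not None:
        if coloring is None:
            raise ValueError("a color multiset requires a coloring")
        table = k_restless_motif_reach(g, coloring, delta, s, motif, opts, engine=engine)
        return (table.earliest(d) is not None, table.earliest(d))
    if k is not None:
        table = k_restless_reach(g, delta, s, k, opts, engine=engine)
        return (table.earliest(d) is not None, table.earliest(d))
    summary = restless_reach(g, delta, s, opts, engine=engine)
    t = summary.min_time.get(d)
    return (t is not None, t)
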