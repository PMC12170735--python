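"""Witness extraction: an optimal restless path in ``k`` oracle queries.

The fine-grained table already pins the endpoint: the smallest timestamp
with a true cell in the destination row is the optimum (path timestamps are
non-decreasing, so the last edge carries the maximum).  The extractor then
walks backwards.  At each step it deletes the current endpoint, removes one
occurrence of its color from the query multiset, caps the horizon at the
current arrival time, and re-queries; any in-neighbor of the endpoint whose
row is true inside the admissible waiting window is a safe predecessor —
its certified prefix is vertex-disjoint from the committed suffix (the
suffix vertices are deleted) and color-compatible (their multiplicities were
removed), so committing it always permits completion.  One query per path
vertex, ``k`` in total.

A dead end can only arise from a sieve false negative; the failing query is
retried with a fresh seed a bounded number of times (at the default 64-bit
field this should never fire in practice).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable

from .problem_reductions import _with_super_source
from .sieve_oracle import SieveOptions, fine_grained_oracle
from .temporal_graph import (
    ColorMultiset,
    RestingTimes,
    RestlessPathWitness,
    TemporalGraph,
    VertexColoring,
)
from .finite_field import prf64

__all__ = ["ExtractionError", "extract_optimal_path", "validate_witness"]

_ROLE_RETRY = 5


class ExtractionError(RuntimeError):
    """Raised when a backward step finds no predecessor after all retries."""


def validate_witness(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    d: int,
    witness: RestlessPathWitness,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
) -> tuple[bool, str | None]:
    """Check a claimed restless path; returns (ok, first violated rule).

    Rules: endpoint identities, vertex distinctness, edge existence, time
    monotonicity, the per-internal-vertex waiting bound, and (when a
    multiset is given) color agreement.
    """
    vs, ts = witness.vertices, witness.times
    if not vs:
        return False, "empty witness"
    if vs[0] != s:
        return False, f"path starts at {vs[0]}, expected source {s}"
    if vs[-1] != d:
        return False, f"path ends at {vs[-1]}, expected destination {d}"
    if len(set(vs)) != len(vs):
        return False, "repeated vertex"
    for i in range(1, len(ts)):
        gap = ts[i] - ts[i - 1]
        if gap < 0:
            return False, f"timestamps decrease at step {i + 1}"
        if gap > delta[vs[i]]:
            return False, (
                f"waiting gap {gap} at vertex {vs[i]} exceeds delta={delta[vs[i]]}"
            )
    for i, t in enumerate(ts):
        u, v = vs[i], vs[i + 1]
        if all(e != (u, v, t) for e in g.edges):
            return False, f"edge ({u},{v},{t}) not in the graph"
    if motif is not None:
        if coloring is None:
            return False, "multiset given without a coloring"
        found = ColorMultiset.from_iterable(coloring[v] for v in vs)
        if found.mu != dict(motif.mu):
            return False, "vertex colors do not agree with the multiset"
    return True, None


def extract_optimal_path(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    d: int,
    opts: SieveOptions,
    k: int | None = None,
    coloring: VertexColoring | None = None,
    motif: ColorMultiset | None = None,
    retries: int = 3,
    engine: str = "numba",
    query_hook: Callable[[], None] | None = None,
) -> RestlessPathWitness | None:
    """Extract a restless path from ``s`` to ``d`` minimizing the last timestamp.

    Plain mode (``k`` given): any ``k``-vertex path, realized internally as
    unit colors with multiset ``{1^k}``.  Motif mode (``coloring`` and
    ``motif`` given): path colors must agree with the multiset.  Returns a
    validated witness, or ``None`` when the initial oracle reports the
    destination unreachable.  ``query_hook`` is invoked once per oracle
    query (the budget is ``k`` per successful attempt, plus retries).
    """
    if d == s:
        raise ValueError("destination must differ from the source")
    if motif is not None:
        if coloring is None:
            raise ValueError("a color multiset requires a coloring")
        k = motif.k
    else:
        if k is None:
            raise ValueError("either k or a color multiset must be given")
        coloring = VertexColoring.unit(g.n)
        motif = ColorMultiset({1: k})
    if k < 2:
        raise ValueError("k must be at least 2")

    g2, delta2, sprime = _with_super_source(g, [s], delta)
    fresh = coloring.num_colors + 1
    coloring2 = VertexColoring.from_list(
        list(coloring.color[1:]) + [fresh], num_colors=fresh
    )

    def query(graph: TemporalGraph, mu: ColorMultiset, ell: int, tau: int, attempt: int):
        seed = opts.seed if attempt == 0 else prf64(opts.seed, (_ROLE_RETRY, ell, attempt))
        if query_hook is not None:
            query_hook()
        return fine_grained_oracle(
            graph, coloring2, delta2, mu,
            replace(opts, ell=ell, tau_limit=tau, seed=seed),
            engine=engine,
        )

    cur_graph = g2
    cur_motif = motif.add(fresh)
    table = query(cur_graph, cur_motif, k + 1, g2.tau, 0)
    times_d = table.row_times(d)
    if not times_d:
        return None
    u_cur, i_cur = d, times_d[0]

    rev_vertices = [d]
    rev_times: list[int] = []
    for ell in range(k + 1, 2, -1):
        pre_deletion = cur_graph
        cur_graph = cur_graph.remove_vertices([u_cur])
        cur_motif = cur_motif.remove_one(coloring2[u_cur])
        candidates_edges = pre_deletion.in_at(u_cur, i_cur)
        chosen: tuple[int, int] | None = None
        for attempt in range(retries + 1):
            sub = query(cur_graph, cur_motif, ell - 1, i_cur, attempt)
            best: tuple[int, int] | None = None
            for v, _ in candidates_edges:
                lo = max(1, i_cur - delta2[v])
                for i in range(lo, i_cur + 1):
                    if sub.reach[v, i]:
                        if best is None or (i, v) < best:
                            best = (i, v)
                        break
            if best is not None:
                chosen = best
                break
        if chosen is None:
            raise ExtractionError(
                f"no predecessor of vertex {u_cur} at time {i_cur} after "
                f"{retries + 1} attempts (sieve false negative?)"
            )
        i_prev, v_prev = chosen
        rev_times.append(i_cur)
        rev_vertices.append(v_prev)
        u_cur, i_cur = v_prev, i_prev

    if u_cur != s:
        raise ExtractionError(f"extraction terminated at {u_cur}, expected source {s}")
    witness = RestlessPathWitness(tuple(reversed(rev_vertices)), tuple(reversed(rev_times)))
    ok, why = validate_witness(g, delta, s, d, witness, coloring=coloring, motif=motif)
    if not ok:
        raise ExtractionError(f"extracted witness failed validation: {why}")
    return witness
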