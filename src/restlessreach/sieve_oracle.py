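"""The constrained multilinear sieve and the fine-grained decision oracle.

The engine encodes every restless walk of ``ell - 1`` edges ending at vertex
``u`` at time ``i`` as a monomial of a generating polynomial, built by a
dynamic program over (time, vertex) cells: level 1 assigns each cell its
vertex variable, and each subsequent level extends walks along in-edges
within the admissible waiting window, tagging every extension with an edge
variable keyed by (edge, level, arrival time).  A walk monomial is
multilinear (no repeated variable) exactly when the walk is a path.

Multilinear monomials are detected by the characteristic-2 sieve: substitute
for each vertex variable a lane sum ``z_u^L`` and XOR the evaluations over
all ``2**ell`` label subsets ``L``.  Monomials with a repeated vertex cancel
*identically*; properly colored multilinear monomials survive with a random
value.  Color multiplicities are enforced through shades: color ``s`` gets
``mu(s)`` shade ids (disjoint across colors) and ``z_{u,j}`` is a
gamma-omega bilinear sum over the shades of ``u``'s color, so a vertex whose
color is absent from the query multiset vanishes from every lane.

The oracle has strictly one-sided error: a reported cell is always backed by
a real properly colored restless path, while a true cell is missed with
probability at most ``(2*ell - 1) * 2**-b`` per repeat.

A pure-Python reference evaluation (`sieve_zeta` with ``engine="python"``)
mirrors the compiled kernel bit for bit and underpins the cross-checks in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import sieve_zeta_kernel
from .finite_field import FieldContext, ff_context, ff_mul, ff_prf, prf64, prf64_bulk
from .temporal_graph import ColorMultiset, RestingTimes, TemporalGraph, VertexColoring

__all__ = [
    "SieveOptions",
    "ShadeAssignment",
    "ReachabilityTable",
    "assign_shades",
    "walk_poly_pass",
    "sieve_zeta",
    "fine_grained_oracle",
    "decide_exists",
]

# PRF role tags keep the random streams of distinct variable families apart.
_ROLE_Y = 1
_ROLE_GAMMA = 2
_ROLE_OMEGA = 3
_ROLE_REPEAT = 4


@dataclass(frozen=True)
class SieveOptions:
    """Evaluation parameters for one oracle run.

    ``ell`` is the number of path vertices (path length ``ell - 1``);
    ``tau_limit`` caps the last-edge timestamp (default: the graph horizon);
    ``repeats`` independent evaluations shrink the false-negative rate
    multiplicatively; ``seed`` drives every random value; ``field_bits``
    selects GF(2^b).
    """

    ell: int
    tau_limit: int | None = None
    repeats: int = 1
    seed: int = 0
    field_bits: int = 64

    def __post_init__(self):
        if self.ell < 1:
            raise ValueError("ell must be at least 1")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass(frozen=True)
class ShadeAssignment:
    """One sieve run's random substitution realizing the color constraints.

    ``shades[s]`` is the tuple of shade ids of color ``s`` (sizes equal the
    query multiplicities, disjoint across colors); ``gamma[(u, d)]`` and
    ``omega[(d, j)]`` are the random field values; ``z[u][j-1]`` is the
    per-vertex, per-label substitution (zero for vertices whose color is
    absent from the multiset).
    """

    shades: dict[int, tuple[int, ...]]
    gamma: dict[tuple[int, int], int]
    omega: dict[tuple[int, int], int]
    z: tuple[tuple[int, ...], ...]  # index [u][j-1]; row 0 unused

    def z_array(self) -> np.ndarray:
        return np.asarray(self.z, dtype=np.uint64)


def assign_shades(
    coloring: VertexColoring,
    motif: ColorMultiset,
    ctx: FieldContext,
    seed: int,
    ell: int,
) -> ShadeAssignment:
    """Draw gamma/omega via the keyed PRF and precompute the z-table."""
    shades: dict[int, tuple[int, ...]] = {}
    next_id = 1
    for color in sorted(motif.mu):
        ids = tuple(range(next_id, next_id + motif.mu[color]))
        shades[color] = ids
        next_id += motif.mu[color]

    gamma: dict[tuple[int, int], int] = {}
    omega: dict[tuple[int, int], int] = {}
    for ids in shades.values():
        for d in ids:
            for j in range(1, ell + 1):
                omega[(d, j)] = ff_prf(ctx, seed, (_ROLE_OMEGA, d, j))
    n = coloring.n
    z_rows: list[tuple[int, ...]] = [(0,) * ell]
    for u in range(1, n + 1):
        ids = shades.get(coloring[u], ())
        for d in ids:
            gamma[(u, d)] = ff_prf(ctx, seed, (_ROLE_GAMMA, u, d))
        row = []
        for j in range(1, ell + 1):
            acc = 0
            for d in ids:
                acc ^= ff_mul(gamma[(u, d)], omega[(d, j)], ctx)
            row.append(acc)
        z_rows.append(tuple(row))
    return ShadeAssignment(shades=shades, gamma=gamma, omega=omega, z=tuple(z_rows))


def walk_poly_pass(
    g: TemporalGraph,
    delta: RestingTimes,
    x_values,
    y_fn,
    ell: int,
    ctx: FieldContext,
    tau_limit: int | None = None,
) -> list[list[int]]:
    """Evaluate the level-``ell`` walk table under one substitution.

    ``x_values[u]`` is the field value substituted for vertex ``u``'s
    variable and ``y_fn(edge_id, level, time)`` supplies edge values.  The
    recursion: level 1 puts ``x_values[u]`` in every cell; level ``l`` sums,
    over in-edges ``(v, u, i)`` and waits ``j <= delta(v)`` with
    ``i - j >= 1``, the product ``y(edge, l-1, i-j) * prev[i-j][v]``, then
    multiplies by ``x_values[u]``.  Returns ``table[i][u]``; reference
    implementation in plain integers.
    """
    tau = g.tau if tau_limit is None else tau_limit
    n = g.n
    table = [[0] * (n + 1) for _ in range(tau + 1)]
    for i in range(1, tau + 1):
        for u in range(1, n + 1):
            table[i][u] = x_values[u]
    for level in range(2, ell + 1):
        new = [[0] * (n + 1) for _ in range(tau + 1)]
        for e, (v, u, t) in enumerate(g.edges):
            if t > tau:
                continue
            acc = 0
            for j in range(delta[v] + 1):
                tp = t - j
                if tp < 1:
                    break
                acc ^= ff_mul(y_fn(e, level - 1, tp), table[tp][v], ctx)
            new[t][u] ^= ff_mul(x_values[u], acc, ctx)
        table = new
    return table


def _y_table(
    g: TemporalGraph,
    delta: RestingTimes,
    ctx: FieldContext,
    seed: int,
    ell: int,
) -> np.ndarray:
    """Precomputed y-values, shape (max(ell-1,1), m, Delta+1).

    ``ytab[l-2, e, j]`` is the value of the edge variable keyed by
    (edge e, level l-1, arrival time t_e - j); entries with t_e - j < 1 are
    never read by the kernel.
    """
    m = g.m
    big_delta = delta.Delta
    levels = max(ell - 1, 1)
    ytab = np.zeros((levels, m, big_delta + 1), dtype=np.uint64)
    if m == 0 or ell < 2:
        return ytab
    _, _, etime = g.edge_arrays()
    eids = np.arange(m, dtype=np.int64)
    mask = np.uint64(ctx.mask)
    for li in range(ell - 1):
        for jj in range(big_delta + 1):
            tp = np.clip(etime - jj, 0, None)
            vals = prf64_bulk(seed, (_ROLE_Y,), eids, np.full(m, li + 1), tp)
            ytab[li, :, jj] = vals & mask
    return ytab


def sieve_zeta(
    g: TemporalGraph,
    coloring: VertexColoring,
    delta: RestingTimes,
    motif: ColorMultiset,
    ctx: FieldContext,
    seed: int,
    ell: int,
    tau_limit: int | None = None,
    engine: str = "numba",
    subset_order: str = "gray",
) -> np.ndarray:
    """One full sieve evaluation: the zeta value of every (time, vertex) cell.

    ``engine="numba"`` runs the compiled Gray-code kernel; ``engine="python"``
    runs the reference path (optionally with naive subset enumeration, which
    must agree by XOR associativity).  Both produce identical uint64 arrays
    of shape (tau_limit+1, n+1).
    """
    tau = g.tau if tau_limit is None else tau_limit
    shade = assign_shades(coloring, motif, ctx, seed, ell)
    if engine == "numba":
        esrc, edst, etime = g.edge_arrays()
        delta_arr = np.asarray(delta.delta, dtype=np.int64)
        ytab = _y_table(g, delta, ctx, seed, ell)
        mod_low = np.uint64(ctx.modulus & ctx.mask)
        mask = np.uint64(ctx.mask)
        high_bit = np.uint64(1 << (ctx.b - 1))
        return sieve_zeta_kernel(
            g.n, tau, ell, esrc, edst, etime, delta_arr,
            shade.z_array(), ytab, mod_low, mask, high_bit,
        )
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    def y_fn(e: int, level: int, tp: int) -> int:
        return ff_prf(ctx, seed, (_ROLE_Y, e, level, tp))

    n = g.n
    zeta = [[0] * (n + 1) for _ in range(tau + 1)]
    if subset_order == "gray":
        zL = [0] * (n + 1)
        for lane in range(1, 1 << ell):
            gg, j = lane, 0
            while gg & 1 == 0:
                gg >>= 1
                j += 1
            for u in range(1, n + 1):
                zL[u] ^= shade.z[u][j]
            table = walk_poly_pass(g, delta, zL, y_fn, ell, ctx, tau)
            for i in range(1, tau + 1):
                for u in range(1, n + 1):
                    zeta[i][u] ^= table[i][u]
    elif subset_order == "naive":
        for lane in range(1, 1 << ell):
            zL = [0] * (n + 1)
            for u in range(1, n + 1):
                for j in range(ell):
                    if lane >> j & 1:
                        zL[u] ^= shade.z[u][j]
            table = walk_poly_pass(g, delta, zL, y_fn, ell, ctx, tau)
            for i in range(1, tau + 1):
                for u in range(1, n + 1):
                    zeta[i][u] ^= table[i][u]
    else:
        raise ValueError(f"unknown subset order {subset_order!r}")
    return np.asarray(zeta, dtype=np.uint64)


@dataclass
class ReachabilityTable:
    """Boolean (vertex x timestamp) output of the fine-grained oracle.

    ``reach[u, i]`` true means some qualifying restless path of the queried
    length ends at ``u`` with last-edge timestamp ``i`` (one-sided
    correctness: true cells are certified up to the sieve's false-negative
    rate, false cells may rarely hide a path).
    """

    reach: np.ndarray  # bool, shape (n+1, tau_limit+1); row/col 0 unused
    ell: int
    tau_limit: int

    @property
    def n(self) -> int:
        return self.reach.shape[0] - 1

    def true_cells(self) -> set[tuple[int, int]]:
        us, ts = np.nonzero(self.reach)
        return set(zip(us.tolist(), ts.tolist()))

    def row_times(self, v: int) -> list[int]:
        return np.nonzero(self.reach[v])[0].tolist()

    def earliest(self, v: int) -> int | None:
        times = self.row_times(v)
        return times[0] if times else None

    def to_tsv(self) -> str:
        lines = ["vertex\ttime"]
        for u, t in sorted(self.true_cells()):
            lines.append(f"{u}\t{t}")
        return "\n".join(lines) + "\n"


def fine_grained_oracle(
    g: TemporalGraph,
    coloring: VertexColoring,
    delta: RestingTimes,
    motif: ColorMultiset,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachabilityTable:
    """Per-(vertex, timestamp) existence of properly colored restless paths.

    Runs ``opts.repeats`` independent sieve evaluations (fresh shades and
    edge values each) and marks a cell as reachable once any evaluation is
    nonzero there.  Requires ``|motif| == opts.ell``.
    """
    if motif.k != opts.ell:
        raise ValueError(f"multiset size {motif.k} must equal ell={opts.ell}")
    if coloring.n != g.n or delta.n != g.n:
        raise ValueError("coloring/resting-time length must match the graph")
    ctx = ff_context(opts.field_bits)
    tau = g.tau if opts.tau_limit is None else opts.tau_limit
    if not (1 <= tau <= g.tau):
        raise ValueError(f"tau_limit must lie in [1, {g.tau}]")
    reach = np.zeros((g.n + 1, tau + 1), dtype=bool)
    for r in range(opts.repeats):
        seed_r = prf64(opts.seed, (_ROLE_REPEAT, r))
        zeta = sieve_zeta(
            g, coloring, delta, motif, ctx, seed_r, opts.ell, tau, engine=engine
        )
        reach |= (zeta != 0).T
    return ReachabilityTable(reach=reach, ell=opts.ell, tau_limit=tau)


def decide_exists(table: ReachabilityTable) -> tuple[bool, dict[int, int]]:
    """Any-true reduction plus per-vertex earliest reachable timestamp."""
    earliest: dict[int, int] = {}
    for v in range(1, table.n + 1):
        t = table.earliest(v)
        if t is not None:
            earliest[v] = t
    return bool(earliest), earliest
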