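"""Random temporal-graph generators and planted-witness instances.

Two configuration-model flavors emulate typical contact-network topologies:
``regular`` pairs ``d`` stubs per vertex uniformly, ``powerlaw`` draws a
degree sequence supported on ``w`` geometrically spaced values with vertex
frequencies proportional to ``degree**alpha`` (``alpha < 0``), the support
scaled so the stub sum approximates ``D * n``.  Edge timestamps are i.i.d.
uniform on ``[1, tau]``.  Self-loops produced by the pairing and exact
duplicate triples are deleted afterwards and their counts reported, so
realized degrees deviate from the target only by the removals.

``plant_instance`` builds graphs containing exactly one restless path
between a designated source and destination — the instrument for measuring
the sieve's false-negative rate on a known witness.

All generators draw from ``numpy.random.default_rng(seed)`` only, so a seed
fixes the instance bit for bit on every platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exhaustive_baseline import enumerate_restless_paths
from .temporal_graph import RestingTimes, RestlessPathWitness, TemporalGraph

__all__ = [
    "GeneratorSpec",
    "GenInfo",
    "gen_regular",
    "gen_powerlaw",
    "gen_resting_times",
    "plant_instance",
    "powerlaw_support",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one random instance.

    ``flavor="regular"`` uses ``d``; ``flavor="powerlaw"`` uses ``D`` (target
    average degree), ``w`` (number of distinct degree values) and ``alpha``
    (negative exponent of the degree-frequency law).
    """

    n: int
    flavor: Literal["regular", "powerlaw"]
    tau: int
    seed: int
    d: int = 0
    D: float = 0.0
    w: int = 0
    alpha: float = -1.0
    directed: bool = True

    def __post_init__(self):
        if self.n < 1 or self.tau < 1:
            raise ValueError("n and tau must be positive")
        if self.flavor == "powerlaw" and self.alpha >= 0:
            raise ValueError("alpha must be negative")


@dataclass(frozen=True)
class GenInfo:
    """Bookkeeping of one generator run: what was targeted, what was removed."""

    stub_sum: int
    loops_removed: int
    duplicates_removed: int
    support: tuple[int, ...] = ()
    support_counts: tuple[int, ...] = ()


def _pair_and_timestamp(
    spec: GeneratorSpec, stubs: np.ndarray, rng: np.random.Generator
) -> tuple[TemporalGraph, GenInfo, tuple[int, ...], tuple[int, ...]]:
    """Uniform stub pairing, timestamping, loop/duplicate removal."""
    rng.shuffle(stubs)
    a = stubs[0::2]
    b = stubs[1::2]
    ts = rng.integers(1, spec.tau + 1, size=a.shape[0])
    triples: list[tuple[int, int, int]] = []
    loops = 0
    for u, v, t in zip(a.tolist(), b.tolist(), ts.tolist()):
        if u == v:
            loops += 2 if not spec.directed else 1
            continue
        if spec.directed:
            triples.append((u, v, t))
        else:
            triples.append((u, v, t))
            triples.append((v, u, t))
    g = TemporalGraph(spec.n, triples, tau=spec.tau)
    info = GenInfo(
        stub_sum=int(stubs.shape[0]),
        loops_removed=loops,
        duplicates_removed=g.duplicates_dropped,
    )
    return g, info, (), ()


def gen_regular(spec: GeneratorSpec) -> tuple[TemporalGraph, GenInfo]:
    """Configuration-model graph with all stub-degrees equal to ``d``.

    In undirected mode each retained pairing becomes two opposing directed
    edges sharing one timestamp, and ``n * d`` must be even.
    """
    if spec.flavor != "regular":
        raise ValueError("spec.flavor must be 'regular'")
    if spec.d < 0:
        raise ValueError("degree must be non-negative")
    if (spec.n * spec.d) % 2 != 0:
        raise ValueError("n * d must be even for stub pairing")
    rng = np.random.default_rng(spec.seed)
    stubs = np.repeat(np.arange(1, spec.n + 1, dtype=np.int64), spec.d)
    g, info, _, _ = _pair_and_timestamp(spec, stubs, rng)
    return g, info


def powerlaw_support(
    n: int, D: float, w: int, alpha: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Degree support, per-value vertex counts, and realized stub sum.

    ``w`` geometrically spaced integer degree values between 1 and a cap;
    vertex counts follow largest-remainder rounding of frequencies
    proportional to ``value**alpha``; the cap is chosen by a deterministic
    grid search so the stub sum lands as close as possible to ``D * n``.
    Rounding may collapse adjacent support values, in which case the support
    has fewer than ``w`` entries.
    """
    target = D * n

    def build(cap: float) -> tuple[np.ndarray, np.ndarray, int]:
        vals = np.unique(np.round(np.geomspace(1.0, cap, w)).astype(np.int64))
        weights = vals.astype(float) ** alpha
        weights /= weights.sum()
        raw = weights * n
        counts = np.floor(raw).astype(np.int64)
        short = n - counts.sum()
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        counts[order[: int(short)]] += 1
        return vals, counts, int((vals * counts).sum())

    best = None
    for cap in np.geomspace(2.0, 1e8, 600):
        vals, counts, s = build(cap)
        err = abs(s - target)
        if best is None or err < best[0]:
            best = (err, vals, counts, s)
        if s > 10 * target:
            break
    assert best is not None
    _, vals, counts, s = best
    return vals, counts, s


def gen_powerlaw(spec: GeneratorSpec) -> tuple[TemporalGraph, GenInfo]:
    """Configuration-model graph with a truncated power-law degree sequence."""
    if spec.flavor != "powerlaw":
        raise ValueError("spec.flavor must be 'powerlaw'")
    if spec.w < 1 or spec.D <= 0:
        raise ValueError("powerlaw flavor needs w >= 1 and D > 0")
    rng = np.random.default_rng(spec.seed)
    vals, counts, stub_sum = powerlaw_support(spec.n, spec.D, spec.w, spec.alpha)
    degree_seq = np.repeat(vals, counts)
    rng.shuffle(degree_seq)  # random vertex <-> degree assignment
    if degree_seq.sum() % 2 != 0:
        warnings.warn("odd stub sum; adding one stub to make pairing feasible")
        degree_seq[0] += 1
    stubs = np.repeat(np.arange(1, spec.n + 1, dtype=np.int64), degree_seq)
    g, info, _, _ = _pair_and_timestamp(spec, stubs, rng)
    info = GenInfo(
        stub_sum=info.stub_sum,
        loops_removed=info.loops_removed,
        duplicates_removed=info.duplicates_removed,
        support=tuple(vals.tolist()),
        support_counts=tuple(counts.tolist()),
    )
    return g, info


def gen_resting_times(
    n: int,
    Delta: int,
    mode: Literal["constant", "uniform"] = "constant",
    source: int | None = None,
    tau: int | None = None,
    seed: int = 0,
) -> RestingTimes:
    """Resting times: constant ``Delta`` or i.i.d. uniform on ``{1..Delta}``.

    With a source given, that vertex gets ``delta = tau`` (an epidemic's
    index case is infectious from the start, so its departure is never
    window-limited).
    """
    if Delta < 1:
        raise ValueError("Delta must be at least 1")
    if mode == "constant":
        d = RestingTimes.constant(n, Delta)
    elif mode == "uniform":
        rng = np.random.default_rng(seed)
        d = RestingTimes.from_map(n, rng.integers(1, Delta + 1, size=n).tolist())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if source is not None:
        if tau is None:
            raise ValueError("source convention requires tau")
        d = d.with_source_unbounded(source, tau)
    return d


def plant_instance(
    n: int,
    k: int,
    tau: int,
    Delta: int,
    extra_edges: int,
    seed: int,
    max_retries: int = 20,
) -> tuple[TemporalGraph, RestingTimes, int, int, RestlessPathWitness]:
    """A graph holding exactly one restless s-to-d path of ``k - 1`` edges.

    A chain over ``k`` random vertices is planted with admissible times
    ending strictly before ``tau``; decoy edges all carry timestamp ``tau``
    and never point into the destination, so no decoy can participate in an
    alternative path ending at the planted cell.  Uniqueness is re-verified
    by exhaustive enumeration; on the (unexpected) failure the instance is
    regenerated from the next sub-seed.
    """
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= n")
    if tau < k:
        raise ValueError("need tau >= k for an admissible planted chain")
    delta = RestingTimes.constant(n, Delta)
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        verts = rng.choice(np.arange(1, n + 1), size=k, replace=False).tolist()
        s, d = verts[0], verts[-1]
        # k-1 edge times with k-2 waiting gaps in {1..Delta}; shrink until the
        # chain ends strictly before tau, then place it at a random offset
        gaps = rng.integers(1, Delta + 1, size=max(k - 2, 0))
        while gaps.size and int(gaps.sum()) > tau - 2 and gaps.max() > 1:
            gaps[int(np.argmax(gaps))] -= 1
        span = int(gaps.sum())
        t1 = 1 + int(rng.integers(0, max(tau - 1 - span - 1, 0) + 1))
        times = (t1 + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)).tolist()
        edges = [(verts[i], verts[i + 1], times[i]) for i in range(k - 1)]
        tried = set(edges)
        added = 0
        guard = 0
        while added < extra_edges and guard < 50 * max(extra_edges, 1):
            guard += 1
            u = int(rng.integers(1, n + 1))
            v = int(rng.integers(1, n + 1))
            if u == v or v == d or (u, v, tau) in tried:
                continue
            tried.add((u, v, tau))
            edges.append((u, v, tau))
            added += 1
        g = TemporalGraph(n, edges, tau=tau)
        witness = RestlessPathWitness(tuple(verts), tuple(times))
        found = enumerate_restless_paths(g, delta, s, k, d=d)
        if len(found) == 1 and found[0] == witness:
            return g, delta, s, d, witness
    raise RuntimeError(f"could not plant a unique witness after {max_retries} attempts")
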