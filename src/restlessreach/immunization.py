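"""Epidemic application layer: reachability under immunized (separator) vertices.

A separator models a vaccinated or quarantined individual: it may appear in
the contact network but no transmission path may pass through it.  This is
enforced algebraically, not by graph surgery — separators receive a color
that is absent from the query multiset, which zeroes their sieve
substitution and silently excludes them from every properly colored path.
(The equivalent explicit-deletion route exists as an internal consistency
check in the test suite.)

Two selection strategies mirror common immunization policies: a uniform
random sample, and the top vertices by temporal degree (contact count).
Random samples are prefixes of one seeded permutation, so plans at
increasing fractions are nested and the resulting reachability series are
pointwise non-increasing by construction.

The reachability series is the cumulative share of non-separator,
non-source vertices first reached by time t — the shape compared across
strategies and fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .problem_reductions import ReachSummary, _summarize
from .sieve_oracle import SieveOptions, fine_grained_oracle
from .temporal_graph import (
    ColorMultiset,
    RestingTimes,
    TemporalGraph,
    VertexColoring,
    temporal_degree,
)

__all__ = [
    "SeparatorPlan",
    "ReachabilitySeries",
    "select_separators",
    "reach_with_separators",
    "reach_series",
]


@dataclass(frozen=True)
class SeparatorPlan:
    """A chosen separator set: strategy, target fraction, selected vertices."""

    strategy: Literal["random", "max_degree"]
    fraction: float
    selected: frozenset[int]


@dataclass(frozen=True)
class ReachabilitySeries:
    """Cumulative reached fraction per timestamp; non-decreasing, in [0, 1]."""

    times: tuple[int, ...]
    ratio: tuple[float, ...]

    def to_tsv(self) -> str:
        lines = ["time\tratio"]
        for t, r in zip(self.times, self.ratio):
            lines.append(f"{t}\t{r:.6f}")
        return "\n".join(lines) + "\n"


def select_separators(
    g: TemporalGraph,
    s: int,
    fraction: float,
    strategy: Literal["random", "max_degree"],
    seed: int = 0,
) -> SeparatorPlan:
    """Choose ``floor(fraction * n)`` separators from ``V \\ {s}``.

    ``random``: a prefix of one seeded permutation (nested across
    fractions for the same seed).  ``max_degree``: highest temporal degree
    first, ties broken by smaller vertex id.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    count = min(int(np.floor(fraction * g.n)), g.n - 1)
    if count == 0:
        warnings.warn("fraction rounds to zero separators")
        return SeparatorPlan(strategy=strategy, fraction=fraction, selected=frozenset())
    candidates = [v for v in range(1, g.n + 1) if v != s]
    if strategy == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(candidates))
        chosen = [candidates[i] for i in perm[:count]]
    elif strategy == "max_degree":
        ranked = sorted(candidates, key=lambda v: (-temporal_degree(g, v), v))
        chosen = ranked[:count]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return SeparatorPlan(strategy=strategy, fraction=fraction, selected=frozenset(chosen))


def reach_with_separators(
    g: TemporalGraph,
    delta: RestingTimes,
    s: int,
    k: int,
    plan: SeparatorPlan,
    opts: SieveOptions,
    engine: str = "numba",
) -> ReachSummary:
    """At-most-``k`` restless reachability from ``s`` avoiding all separators.

    Colors: separators 3, source 2, everyone else 1; for each length the
    multiset ``{1^(l-1), 2}`` omits color 3 entirely, so separators vanish
    from the sieve.  The source's in-edges are removed to pin the origin.
    """
    if s in plan.selected:
        raise ValueError("the source cannot be a separator")
    if k < 2:
        raise ValueError("k must be at least 2")
    colors = [1] * g.n
    for v in plan.selected:
        colors[v - 1] = 3
    colors[s - 1] = 2
    coloring = VertexColoring.from_list(colors, num_colors=3)
    g2 = g.remove_in_edges(s)
    tables = {}
    for ell in range(2, min(k, g.n) + 1):
        motif = ColorMultiset({1: ell - 1, 2: 1})
        table = fine_grained_oracle(
            g2, coloring, delta, motif, replace(opts, ell=ell), engine=engine
        )
        table.reach[s] = False
        tables[ell] = table
    return _summarize(g.n, s, tables)


def reach_series(
    summary: ReachSummary, plan: SeparatorPlan, n: int, s: int
) -> ReachabilitySeries:
    """Cumulative reached fraction over non-separator, non-source vertices."""
    denom = n - len(plan.selected) - 1
    if denom <= 0:
        raise ValueError("no vertices left to reach (denominator is zero)")
    times = sorted(
        t for v, t in summary.min_time.items() if v != s and v not in plan.selected
    )
    uniq: list[int] = []
    ratio: list[float] = []
    seen = 0
    for t in times:
        seen += 1
        if uniq and uniq[-1] == t:
            ratio[-1] = seen / denom
        else:
            uniq.append(t)
            ratio.append(seen / denom)
    return ReachabilitySeries(times=tuple(uniq), ratio=tuple(ratio))
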