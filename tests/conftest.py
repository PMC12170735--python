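"""Shared fixtures: the hand-enumerable five-vertex instance and random-instance factories."""

import numpy as np
import pytest

from restlessreach.temporal_graph import (
    ColorMultiset,
    RestingTimes,
    TemporalGraph,
    VertexColoring,
    five_vertex_example,
)


@pytest.fixture
def fixture5():
    """Five-vertex documentation instance: graph and constant resting time 2."""
    return five_vertex_example()


def make_random_instance(rng, n_range=(4, 13), m_factor=5, tau_range=(3, 9), delta_range=(1, 4)):
    """A small random temporal graph with per-vertex resting times."""
    n = int(rng.integers(*n_range))
    m = int(rng.integers(n, m_factor * n + 1))
    tau = int(rng.integers(*tau_range))
    Delta = int(rng.integers(*delta_range))
    edges = []
    seen = set()
    attempts = 0
    while len(edges) < m and attempts < 50 * m:
        attempts += 1
        u = int(rng.integers(1, n + 1))
        v = int(rng.integers(1, n + 1))
        t = int(rng.integers(1, tau + 1))
        if u == v or (u, v, t) in seen:
            continue
        seen.add((u, v, t))
        edges.append((u, v, t))
    g = TemporalGraph(n, edges, tau=tau)
    delta = RestingTimes.from_map(n, rng.integers(1, Delta + 1, size=n).tolist())
    return g, delta


def make_random_coloring(rng, n, max_colors=3):
    num = int(rng.integers(1, max_colors + 1))
    return VertexColoring.from_list(rng.integers(1, num + 1, size=n).tolist(), num_colors=num)


def make_feasible_motif(rng, coloring, k):
    """A size-k color multiset drawn from colors actually present in the graph."""
    present = sorted(set(coloring.color[1:]))
    picks = rng.choice(present, size=k, replace=True).tolist()
    return ColorMultiset.from_iterable(int(c) for c in picks)


@pytest.fixture
def random_instance():
    return make_random_instance


@pytest.fixture
def random_coloring():
    return make_random_coloring


@pytest.fixture
def feasible_motif():
    return make_feasible_motif
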