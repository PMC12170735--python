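"""Reachability problem reductions around the fine-grained oracle."""

import numpy as np
import pytest

from restlessreach.exhaustive_baseline import brute_reach_cells
from restlessreach.problem_reductions import (
    atm_k_restless_reach,
    k_restless_motif_reach,
    k_restless_reach,
    multi_source,
    restless_reach,
    st_decision,
)
from restlessreach.sieve_oracle import SieveOptions
from restlessreach.temporal_graph import (
    ColorMultiset,
    RestingTimes,
    TemporalGraph,
    VertexColoring,
)
from conftest import make_random_instance

OPTS = SieveOptions(ell=2, repeats=3, seed=77)


class TestExactLength:
    def test_fixture_k4_and_k2(self, fixture5):
        g, delta = fixture5
        assert k_restless_reach(g, delta, 1, 4, OPTS).true_cells() == {(4, 3)}
        assert k_restless_reach(g, delta, 1, 2, OPTS).true_cells() == {(2, 1)}

    def test_source_without_out_edges(self, fixture5):
        g, delta = fixture5
        assert not k_restless_reach(g, delta, 5, 2, OPTS).reach.any()

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(12)
        for i in range(25):
            g, delta = make_random_instance(rng, n_range=(4, 10), tau_range=(3, 7))
            s = int(rng.integers(1, g.n + 1))
            k = int(rng.integers(2, min(6, g.n) + 1))
            tab = k_restless_reach(g, delta, s, k, SieveOptions(ell=2, repeats=3, seed=i))
            assert tab.true_cells() == brute_reach_cells(g, delta, s, k)


class TestMotifReach:
    COL = VertexColoring.from_list([1, 2, 1, 2, 3], num_colors=3)

    def test_fixture_matching_multiset(self, fixture5):
        g, delta = fixture5
        m = ColorMultiset.from_iterable([1, 2, 1, 2])
        tab = k_restless_motif_reach(g, self.COL, delta, 1, m, OPTS)
        assert tab.true_cells() == {(4, 3)}

    def test_fixture_unmatched_multiset(self, fixture5):
        g, delta = fixture5
        m = ColorMultiset.from_iterable([1, 2, 2, 3])
        tab = k_restless_motif_reach(g, self.COL, delta, 1, m, OPTS)
        assert not tab.reach.any()

    def test_isolated_source_warns_all_false(self, fixture5):
        g, delta = fixture5
        with pytest.warns(UserWarning, match="no out-edges"):
            tab = k_restless_motif_reach(
                g, self.COL, delta, 5, ColorMultiset({3: 1, 2: 1}), OPTS
            )
        assert not tab.reach.any()

    def test_super_source_and_recoloring_agree_on_plain_instances(self):
        # super-source and source-recoloring constructions, same tables
        rng = np.random.default_rng(21)
        for i in range(20):
            g, delta = make_random_instance(rng, n_range=(4, 9), tau_range=(3, 6))
            s = int(rng.integers(1, g.n + 1))
            k = int(rng.integers(2, min(5, g.n) + 1))
            opts = SieveOptions(ell=2, repeats=3, seed=300 + i)
            plain = k_restless_reach(g, delta, s, k, opts)
            unit = VertexColoring.unit(g.n)
            motif = k_restless_motif_reach(g, unit, delta, s, ColorMultiset({1: k}), opts)
            assert plain.true_cells() == motif.true_cells()


class TestAtMostAndFull:
    def test_fixture_union(self, fixture5):
        g, delta = fixture5
        s = atm_k_restless_reach(g, delta, 1, 4, OPTS)
        assert s.min_time == {2: 1, 3: 2, 4: 3}
        assert s.min_length == {2: 1, 3: 2, 4: 3}
        assert 5 not in s.reached

    def test_summary_is_or_of_tables(self, fixture5):
        g, delta = fixture5
        s = atm_k_restless_reach(g, delta, 3, 5, OPTS)
        for v in range(1, 6):
            times = [t for tab in s.tables.values() for t in tab.row_times(v)]
            if times:
                assert s.min_time[v] == min(times)
            else:
                assert v not in s.min_time

    def test_chain_graph_lengths(self):
        n = 6
        g = TemporalGraph(n, [(i, i + 1, i) for i in range(1, n)], tau=n)
        delta = RestingTimes.constant(n, 1)
        s = atm_k_restless_reach(g, delta, 1, n, OPTS)
        assert s.min_length == {v: v - 1 for v in range(2, n + 1)}

    def test_full_reach_fixture(self, fixture5):
        g, delta = fixture5
        assert restless_reach(g, delta, 1, OPTS).min_time == {2: 1, 3: 2, 4: 3}
        s3 = restless_reach(g, delta, 3, OPTS)
        assert s3.min_time == {4: 3, 2: 4, 5: 5}
        assert s3.min_length == {4: 1, 2: 2, 5: 3}

    def test_nesting_in_k(self):
        rng = np.random.default_rng(31)
        for i in range(10):
            g, delta = make_random_instance(rng, n_range=(4, 9), tau_range=(3, 6))
            s = int(rng.integers(1, g.n + 1))
            opts = SieveOptions(ell=2, repeats=3, seed=400 + i)
            k = min(4, g.n)
            small = atm_k_restless_reach(g, delta, s, k - 1, opts) if k >= 3 else None
            big = atm_k_restless_reach(g, delta, s, k, opts)
            if small is not None:
                assert small.reached <= big.reached

    def test_delta_monotonicity(self):
        rng = np.random.default_rng(41)
        for i in range(10):
            g, delta = make_random_instance(rng, n_range=(4, 9), tau_range=(3, 6))
            s = int(rng.integers(1, g.n + 1))
            bumped = RestingTimes.from_map(g.n, [delta[v] + 1 for v in range(1, g.n + 1)])
            opts = SieveOptions(ell=2, repeats=3, seed=500 + i)
            lo = restless_reach(g, delta, s, opts)
            hi = restless_reach(g, bumped, s, opts)
            assert lo.reached <= hi.reached

    def test_empty_graph(self):
        g = TemporalGraph(3, [], tau=1)
        s = restless_reach(g, RestingTimes.constant(3, 1), 1, OPTS)
        assert s.min_time == {}


class TestMultiSource:
    def test_singleton_equals_single_source(self, fixture5):
        g, delta = fixture5
        single = restless_reach(g, delta, 1, OPTS)
        multi = multi_source(g, delta, [1], OPTS)
        assert multi.min_time == single.min_time
        assert multi.min_length == single.min_length

    def test_union_of_sources(self, fixture5):
        g, delta = fixture5
        multi = multi_source(g, delta, [1, 3], OPTS)
        s1 = restless_reach(g, delta, 1, OPTS)
        s3 = restless_reach(g, delta, 3, OPTS)
        expected = {}
        for summ in (s1, s3):
            for v, t in summ.min_time.items():
                expected[v] = min(t, expected.get(v, t))
        assert multi.min_time == expected

    def test_all_sources(self, fixture5):
        g, delta = fixture5
        multi = multi_source(g, delta, [1, 2, 3, 4, 5], OPTS)
        per_source = {}
        for s in range(1, 6):
            for v, t in restless_reach(g, delta, s, OPTS).min_time.items():
                per_source[v] = min(t, per_source.get(v, t))
        assert multi.min_time == per_source


class TestStDecision:
    def test_fixture_decisions(self, fixture5):
        g, delta = fixture5
        assert st_decision(g, delta, 1, 4, OPTS, k=4) == (True, 3)
        assert st_decision(g, delta, 1, 5, OPTS, k=4) == (False, None)
        assert st_decision(g, delta, 1, 5, OPTS) == (False, None)
        assert st_decision(g, delta, 3, 5, OPTS) == (True, 5)

    def test_same_endpoints_rejected(self, fixture5):
        g, delta = fixture5
        with pytest.raises(ValueError, match="differ"):
            st_decision(g, delta, 2, 2, OPTS)
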