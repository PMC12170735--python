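"""The multilinear sieve: shades, walk polynomial, fine-grained oracle."""

import numpy as np
import pytest

from restlessreach.exhaustive_baseline import brute_reach_cells, enumerate_restless_paths
from restlessreach.finite_field import ff_context, ff_mul, ff_prf
from restlessreach.sieve_oracle import (
    ReachabilityTable,
    SieveOptions,
    assign_shades,
    decide_exists,
    fine_grained_oracle,
    sieve_zeta,
    walk_poly_pass,
)
from restlessreach.temporal_graph import (
    ColorMultiset,
    RestingTimes,
    TemporalGraph,
    VertexColoring,
)
from conftest import make_feasible_motif, make_random_coloring, make_random_instance

CTX = ff_context(64)
UNIT5 = VertexColoring.unit(5)
M4 = ColorMultiset({1: 4})


class TestShades:
    def test_shade_sets_sizes_and_disjointness(self):
        col = VertexColoring.from_list([1, 1, 2])
        sh = assign_shades(col, ColorMultiset({1: 2, 2: 1}), CTX, seed=3, ell=3)
        assert len(sh.shades[1]) == 2 and len(sh.shades[2]) == 1
        assert not set(sh.shades[1]) & set(sh.shades[2])

    def test_absent_color_gets_zero_substitution(self):
        col = VertexColoring.from_list([1, 3, 1], num_colors=3)
        sh = assign_shades(col, ColorMultiset({1: 2, 2: 1}), CTX, seed=3, ell=3)
        assert sh.z[2] == (0, 0, 0)
        assert any(sh.z[1]) and any(sh.z[3])

    def test_deterministic_under_seed(self):
        col = VertexColoring.from_list([1, 2, 1])
        m = ColorMultiset({1: 2, 2: 1})
        a = assign_shades(col, m, CTX, seed=7, ell=3)
        b = assign_shades(col, m, CTX, seed=7, ell=3)
        c = assign_shades(col, m, CTX, seed=8, ell=3)
        assert a.z == b.z and a.z != c.z

    def test_bilinear_identity(self):
        # z_{u,j} must equal the gamma-omega sum over the vertex's shades
        col = VertexColoring.from_list([2, 1, 1])
        m = ColorMultiset({1: 2, 2: 1})
        sh = assign_shades(col, m, CTX, seed=5, ell=3)
        for u in range(1, 4):
            for j in range(1, 4):
                acc = 0
                for d in sh.shades[col[u]]:
                    acc ^= ff_mul(sh.gamma[(u, d)], sh.omega[(d, j)], CTX)
                assert sh.z[u][j - 1] == acc


class TestWalkPolynomial:
    def test_level_one_is_the_substitution(self, fixture5):
        g, delta = fixture5
        x = {u: 100 + u for u in range(1, 6)}
        t = walk_poly_pass(g, delta, x, lambda e, l, tp: 1, 1, CTX)
        for i in range(1, 6):
            for u in range(1, 6):
                assert t[i][u] == x[u]

    def test_single_edge_product_structure(self):
        # one edge (1,2,3), delta(1)=1: level-2 cell (3,2) sums the two
        # admissible waits, x2*(y(3)*x1 + y(2)*x1), with y keyed by arrival
        g = TemporalGraph(2, [(1, 2, 3)], tau=4)
        delta = RestingTimes.constant(2, 1)
        x = {1: 7, 2: 9}
        y = lambda e, l, tp: 1000 + tp
        t = walk_poly_pass(g, delta, x, y, 2, CTX)
        expect = ff_mul(
            x[2],
            ff_mul(1003, x[1], CTX) ^ ff_mul(1002, x[1], CTX),
            CTX,
        )
        assert t[3][2] == expect and expect != 0
        assert t[3][1] == 0 and t[2][2] == 0

    def test_constant_edge_values_cancel_waits_pairwise(self):
        # with an even waiting window and identical y values the two lanes of
        # the window XOR away -- the reason edge variables carry arrival times
        g = TemporalGraph(2, [(1, 2, 3)], tau=4)
        delta = RestingTimes.constant(2, 1)
        t = walk_poly_pass(g, delta, {1: 7, 2: 9}, lambda e, l, tp: 5, 2, CTX)
        assert t[3][2] == 0

    def test_no_in_edge_cell_is_zero(self, fixture5):
        g, delta = fixture5
        x = {u: u + 1 for u in range(1, 6)}
        t = walk_poly_pass(g, delta, x, lambda e, l, tp: 3, 2, CTX)
        assert all(t[i][1] == 0 for i in range(1, 6))  # v1 has no in-edges


class TestEngineAgreement:
    def test_numba_matches_python_and_subset_orders(self):
        rng = np.random.default_rng(2)
        for i in range(8):
            g, delta = make_random_instance(rng, n_range=(4, 8), tau_range=(3, 6))
            col = make_random_coloring(rng, g.n)
            ell = int(rng.integers(2, 5))
            motif = make_feasible_motif(rng, col, ell)
            zn = sieve_zeta(g, col, delta, motif, CTX, 50 + i, ell, engine="numba")
            zp = sieve_zeta(g, col, delta, motif, CTX, 50 + i, ell, engine="python")
            zq = sieve_zeta(
                g, col, delta, motif, CTX, 50 + i, ell, engine="python", subset_order="naive"
            )
            assert (zn == zp).all()
            assert (zp == zq).all()


class TestOracle:
    def test_fixture_length_three_cells(self, fixture5):
        g, delta = fixture5
        tab = fine_grained_oracle(g, UNIT5, delta, M4, SieveOptions(ell=4, repeats=3, seed=1))
        assert tab.true_cells() == {(4, 3), (5, 5)}

    def test_fixture_length_five_walk_cancels(self, fixture5):
        # the only length-5 restless walk into v5 revisits v2, so every cell
        # cancels identically regardless of the seed
        g, delta = fixture5
        m6 = ColorMultiset({1: 6})
        for seed in range(50):
            tab = fine_grained_oracle(
                g, UNIT5, delta, m6, SieveOptions(ell=6, repeats=1, seed=seed)
            )
            assert not tab.reach.any()

    def test_single_vertex_base_case(self, fixture5):
        g, delta = fixture5
        col = VertexColoring.from_list([1, 2, 1, 1, 1], num_colors=2)
        tab = fine_grained_oracle(
            g, col, delta, ColorMultiset({2: 1}), SieveOptions(ell=1, repeats=2, seed=4)
        )
        assert tab.true_cells() == {(2, i) for i in range(1, 6)}

    def test_motif_size_must_match_ell(self, fixture5):
        g, delta = fixture5
        with pytest.raises(ValueError, match="must equal ell"):
            fine_grained_oracle(g, UNIT5, delta, M4, SieveOptions(ell=3, seed=0))

    def test_tau_limit_truncates_cells(self, fixture5):
        g, delta = fixture5
        tab = fine_grained_oracle(
            g, UNIT5, delta, M4, SieveOptions(ell=4, repeats=3, seed=1, tau_limit=4)
        )
        assert tab.true_cells() == {(4, 3)}

    def test_matches_brute_force_on_random_colored_instances(self):
        rng = np.random.default_rng(33)
        for i in range(40):
            g, delta = make_random_instance(rng, n_range=(4, 10), tau_range=(3, 7))
            col = make_random_coloring(rng, g.n)
            ell = int(rng.integers(2, 5))
            motif = make_feasible_motif(rng, col, ell)
            tab = fine_grained_oracle(
                g, col, delta, motif, SieveOptions(ell=ell, repeats=3, seed=1000 + i)
            )
            expected = set()
            for s in range(1, g.n + 1):
                expected |= brute_reach_cells(g, delta, s, ell, coloring=col, motif=motif)
            assert tab.true_cells() == expected

    def test_edge_addition_never_loses_cells(self):
        rng = np.random.default_rng(8)
        for i in range(15):
            g, delta = make_random_instance(rng, n_range=(4, 8), tau_range=(3, 6))
            # drop one random edge to form the smaller instance
            drop = int(rng.integers(0, g.m))
            g_small = TemporalGraph(g.n, [e for j, e in enumerate(g.edges) if j != drop], tau=g.tau)
            col = VertexColoring.unit(g.n)
            motif = ColorMultiset({1: 3})
            opts = SieveOptions(ell=3, repeats=3, seed=200 + i)
            small = fine_grained_oracle(g_small, col, delta, motif, opts)
            big = fine_grained_oracle(g, col, delta, motif, opts)
            assert small.true_cells() <= big.true_cells()

    def test_decide_exists_reductions(self, fixture5):
        g, delta = fixture5
        tab = fine_grained_oracle(g, UNIT5, delta, M4, SieveOptions(ell=4, repeats=3, seed=1))
        any_true, earliest = decide_exists(tab)
        assert any_true and earliest == {4: 3, 5: 5}
        empty = ReachabilityTable(np.zeros((6, 6), dtype=bool), ell=4, tau_limit=5)
        assert decide_exists(empty) == (False, {})


class TestFalseNegativeRate:
    def test_planted_witness_miss_rate_small_field(self):
        # b = 8, one repeat: per-cell miss probability bounded by (2*4-1)/2^8
        from restlessreach.problem_reductions import k_restless_reach
        from restlessreach.synthetic_generators import plant_instance

        trials = 2000
        miss = 0
        for i in range(trials):
            g, delta, s, d, w = plant_instance(8, 4, 8, 2, 8, seed=i)
            opts = SieveOptions(ell=2, repeats=1, seed=7_000_000 + i, field_bits=8)
            tab = k_restless_reach(g, delta, s, 4, opts)
            if not tab.reach[d, w.times[-1]]:
                miss += 1
        p = 7 / 256
        bound = p + 4 * np.sqrt(p * (1 - p) / trials)
        assert miss / trials <= bound
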