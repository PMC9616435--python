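"""Exact multiplier solver: fixed points, oracles and gauge behavior."""

import itertools

import numpy as np
import pytest

import fcbm
from fcbm.exact import probability_matrix, residuals
from conftest import random_valid_configuration


def _solve_uniform_block(N, p):
    part = fcbm.BlockPartition(assignment=np.zeros(N, dtype=int))
    delta = fcbm.MixingDensityMatrix(np.array([[2.0]]))
    c = fcbm.build_constraints(p, delta, np.ones(N), part)
    return fcbm.solve_fcbm(c, part), c, part


class TestEdgeProbability:
    def test_logistic_at_unit_multipliers(self):
        assert fcbm.edge_probability(1.0, 1.0, 1.0) == 0.5

    def test_same_vertex_probability_is_zero(self):
        assert fcbm.edge_probability(5.0, 5.0, 5.0, same_vertex=True) == 0.0

    def test_small_argument_linearization(self):
        t = 1e-9
        assert fcbm.edge_probability(t, 1.0, 1.0) == pytest.approx(t, rel=1e-8)


class TestErdosRenyiReduction:
    @pytest.mark.parametrize("p", [0.05, 0.3, 0.7])
    def test_single_block_uniform_fitness_gives_constant_probability(self, p):
        (m, report), c, part = _solve_uniform_block(8, p)
        assert report.converged
        P = probability_matrix(m)
        off = P[~np.eye(8, dtype=bool)]
        np.testing.assert_allclose(off, p, rtol=1e-6)


class TestResiduals:
    def test_residuals_vanish_at_analytic_fixed_point(self):
        N, p = 6, 0.4
        part = fcbm.BlockPartition(assignment=np.zeros(N, dtype=int))
        delta = fcbm.MixingDensityMatrix(np.array([[2.0]]))
        c = fcbm.build_constraints(p, delta, np.ones(N), part)
        # x_i x_j y / (1 + x_i x_j y) = p for x = 1, y = p/(1-p)
        m = fcbm.MultiplierSet(
            x=np.ones(N), y=np.array([[p / (1 - p)]]), part=part
        )
        r_K, r_k = residuals(m, c, part)
        np.testing.assert_allclose(r_K, 0.0, atol=1e-12)
        np.testing.assert_allclose(r_k, 0.0, atol=1e-12)

    def test_zero_multipliers_give_minus_target_residuals(
        self, two_block_constraints, two_block_partition
    ):
        m = fcbm.MultiplierSet(
            x=np.zeros(4), y=np.zeros((2, 2)), part=two_block_partition
        )
        r_K, r_k = residuals(m, two_block_constraints, two_block_partition)
        np.testing.assert_allclose(r_K, -two_block_constraints.K)
        np.testing.assert_allclose(r_k, -two_block_constraints.k)

    def test_vertex_residual_increases_with_its_multiplier(
        self, two_block_constraints, two_block_partition
    ):
        m, _ = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        x2 = m.x.copy()
        x2[0] *= 1.5
        bumped = fcbm.MultiplierSet(x=x2, y=m.y, part=two_block_partition)
        _, r_k0 = residuals(m, two_block_constraints, two_block_partition)
        _, r_k1 = residuals(bumped, two_block_constraints, two_block_partition)
        assert r_k1[0] > r_k0[0]


class TestSolver:
    def test_two_block_toy_converges_and_self_checks(
        self, two_block_constraints, two_block_partition
    ):
        m, report = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        assert report.converged
        r_K, r_k = residuals(m, two_block_constraints, two_block_partition)
        assert max(np.abs(r_K).max(), np.abs(r_k).max()) <= 1e-7

    def test_heterogeneous_fitness_three_blocks_converges(self):
        rng = np.random.default_rng(5)
        p, delta, f, part = random_valid_configuration(rng, N=30, n=3)
        c = fcbm.build_constraints(p, delta, f, part)
        m, report = fcbm.solve_fcbm(c, part, tol=1e-8)
        assert report.converged
        assert report.max_residual <= 1e-8

    def test_regular_graph_constraints_force_uniform_multipliers(self):
        part = fcbm.BlockPartition(assignment=np.zeros(6, dtype=int))
        c = fcbm.ConstraintSet(K=np.array([[12.0]]), k=np.full(6, 2.0), part=part)
        m, report = fcbm.solve_dcbm(c, part)
        assert report.converged
        np.testing.assert_allclose(m.x, m.x[0], rtol=1e-9)

    def test_four_cycle_constraints_reproduce_degrees(self):
        part = fcbm.BlockPartition(assignment=np.zeros(4, dtype=int))
        c = fcbm.ConstraintSet(K=np.array([[8.0]]), k=np.full(4, 2.0), part=part)
        m, report = fcbm.solve_dcbm(c, part)
        assert report.converged
        np.testing.assert_allclose(probability_matrix(m).sum(axis=1), 2.0, rtol=1e-7)

    def test_infeasible_degree_rejected_before_iteration(self):
        part = fcbm.BlockPartition(assignment=np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="infeasible"):
            fcbm.ConstraintSet(
                K=np.array([[10.0]]), k=np.array([5.0, 3.0, 1.0, 1.0]), part=part
            )

    def test_deterministic_given_identical_inputs(
        self, two_block_constraints, two_block_partition
    ):
        m1, _ = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        m2, _ = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        np.testing.assert_array_equal(m1.x, m2.x)
        np.testing.assert_array_equal(m1.y, m2.y)

    def test_zero_degree_vertex_pinned_at_zero(self):
        part = fcbm.BlockPartition(assignment=np.zeros(5, dtype=int))
        import networkx as nx

        g = nx.cycle_graph(4)  # vertex 4 isolated
        g.add_node(4)
        c = fcbm.constraints_from_graph(g, part)
        m, report = fcbm.solve_dcbm(c, part)
        assert report.converged
        assert m.x[4] == 0.0
        assert probability_matrix(m)[4].sum() == 0.0


class TestSymmetryAndGauge:
    def test_equal_fitness_within_block_gives_equal_multipliers(self):
        part = fcbm.BlockPartition(assignment=np.array([0, 0, 0, 1, 1, 1]))
        delta = fcbm.MixingDensityMatrix(
            np.array([[0.9, 0.3], [0.3, 0.5]])
        )
        f = np.array([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
        c = fcbm.build_constraints(0.15, delta, f, part)
        m, report = fcbm.solve_fcbm(c, part)
        assert report.converged
        np.testing.assert_allclose(m.x[:3], m.x[0], rtol=1e-9)
        np.testing.assert_allclose(m.x[3:], m.x[3], rtol=1e-9)

    def test_gauge_rescaling_leaves_probabilities_unchanged(
        self, two_block_constraints, two_block_partition
    ):
        m, _ = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        scale = np.array([3.0, 0.5])
        a = two_block_partition.assignment
        x2 = m.x * scale[a]
        y2 = m.y / np.outer(scale, scale)
        m2 = fcbm.MultiplierSet(x=x2, y=y2, part=two_block_partition)
        np.testing.assert_allclose(
            probability_matrix(m), probability_matrix(m2), rtol=1e-12
        )

    def test_gauge_fixed_output_block_sums_match_degree_totals(
        self, two_block_constraints, two_block_partition
    ):
        m, _ = fcbm.solve_fcbm(two_block_constraints, two_block_partition)
        a = two_block_partition.assignment
        bx = np.bincount(a, weights=m.x)
        bk = np.bincount(a, weights=two_block_constraints.k)
        np.testing.assert_allclose(bx, bk, rtol=1e-12)


class TestEnumerationOracle:
    def test_ensemble_expectations_by_exhaustive_enumeration(self):
        """Expected degrees/link counts over all 2^C(N,2) graphs equal the
        analytic pair-probability sums at machine precision."""
        rng = np.random.default_rng(3)
        part = fcbm.BlockPartition(assignment=np.array([0, 0, 0, 1, 1]))
        delta = fcbm.MixingDensityMatrix(
            np.array([[0.9, 0.45], [0.45, 0.2]])
        )
        f = rng.lognormal(sigma=0.3, size=5)
        c = fcbm.build_constraints(0.25, delta, f, part)
        m, report = fcbm.solve_fcbm(c, part)
        assert report.converged
        N = part.N
        pairs = list(itertools.combinations(range(N), 2))
        P = probability_matrix(m)
        exp_deg = np.zeros(N)
        exp_L = np.zeros((part.n, part.n))
        total_prob = 0.0
        for bits in itertools.product([0, 1], repeat=len(pairs)):
            prob = 1.0
            deg = np.zeros(N)
            L = np.zeros((part.n, part.n))
            for (i, j), b in zip(pairs, bits):
                prob *= P[i, j] if b else (1.0 - P[i, j])
                if b:
                    deg[i] += 1
                    deg[j] += 1
                    I, J = part.assignment[i], part.assignment[j]
                    L[I, J] += 1
                    L[J, I] += 1
            total_prob += prob
            exp_deg += prob * deg
            exp_L += prob * L
        assert total_prob == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(exp_deg, P.sum(axis=1), atol=1e-12)
        # and the solved model meets the constraints
        np.testing.assert_allclose(exp_deg, c.k, atol=1e-7)
        np.testing.assert_allclose(exp_L, c.K, atol=1e-7)


class TestSparseLimit:
    """As density vanishes the closed form approaches the exact solution,
    except for the intra-block self-pair term the closed form drops: that
    deviation is pinned at an O(1/N_I) floor independent of density (the
    single-block reduction makes this exact: sparse gives p(N-1)/N against
    the exact value p at every density)."""

    def _config(self):
        rng = np.random.default_rng(60)
        N, n = 60, 3
        assignment = np.concatenate([np.arange(n), rng.integers(0, n, N - n)])
        part = fcbm.BlockPartition(assignment=assignment, n=n)
        w = rng.random((n, n)) + 0.3
        w = (w + w.T) / 2
        delta = fcbm.MixingDensityMatrix(w / w.sum() * 2.0)
        return part, delta

    def _deviations(self, part, delta, f):
        cross_devs, intra_devs = [], []
        a = part.assignment
        N = part.N
        same = np.equal.outer(a, a) & ~np.eye(N, dtype=bool)
        cross = ~np.equal.outer(a, a)
        for p in [0.1, 0.01, 0.001]:
            c = fcbm.build_constraints(p, delta, f, part)
            m, report = fcbm.solve_fcbm(c, part)
            assert report.converged
            sp = fcbm.sparse_multipliers_fcbm(c, part)
            idx = np.arange(N)
            rel = np.abs(sp.probability_block(idx, idx) - probability_matrix(m))
            rel = rel / np.where(probability_matrix(m) > 0, probability_matrix(m), 1.0)
            cross_devs.append(rel[cross].max())
            intra_devs.append(rel[same].max())
        return cross_devs, intra_devs

    def test_cross_block_deviation_vanishes_monotonically(self):
        # uniform fitness isolates the linearization error, which is the
        # part that vanishes with density; fitness heterogeneity adds its
        # own density-independent O(max_i k_i / D_I) term
        part, delta = self._config()
        cross, _ = self._deviations(part, delta, np.ones(part.N))
        assert cross[0] > cross[1] > cross[2]
        assert cross[2] < 1e-6

    def test_intra_block_deviation_is_pinned_at_self_pair_floor(self):
        part, delta = self._config()
        _, intra = self._deviations(part, delta, np.ones(part.N))
        # uniform fitness: floor is exactly 1/min(N_I) at every density
        floor = 1.0 / part.sizes.min()
        np.testing.assert_allclose(intra, floor, rtol=1e-5)
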