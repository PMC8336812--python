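"""Design matrices, penalties, constraints and effect coding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from distreg.bases import (
    DistrictGraph,
    PenaltyMatrix,
    SplineBasisDef,
    apply_sum_to_zero_constraint,
    build_bspline_basis,
    build_difference_penalty,
    build_mrf_penalty,
    build_tensor_basis,
    effect_code,
    read_district_graph,
    spline_def_for,
    write_district_graph,
)


class TestBSplineBasis:
    def test_partition_of_unity_and_range(self):
        bd = SplineBasisDef("x", degree=3, n_intervals=10, boundary=(0.0, 1.0))
        x = np.linspace(0, 1, 200)
        B = build_bspline_basis(x, bd)
        assert B.shape == (200, 13)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12
        assert B.min() >= 0.0 and B.max() <= 1.0

    def test_degree1_hand_value(self):
        # x = 0.5 sits on the interior knot of a degree-1 basis with two
        # intervals: the middle hat function is exactly 1 there
        bd = SplineBasisDef("x", degree=1, n_intervals=2, boundary=(0.0, 1.0),
                            penalty_order=1)
        row = build_bspline_basis(np.array([0.5]), bd)[0]
        assert np.allclose(row, [0.0, 1.0, 0.0])

    def test_out_of_range_names_covariate(self):
        bd = SplineBasisDef("age_months", degree=3, n_intervals=5, boundary=(0.0, 1.0))
        with pytest.raises(ValueError, match="age_months"):
            build_bspline_basis(np.array([0.5, 1.7]), bd)

    @given(st.integers(1, 4), st.integers(4, 15), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_partition_of_unity_property(self, degree, n_intervals, seed):
        rng = np.random.default_rng(seed)
        bd = SplineBasisDef("x", degree=degree, n_intervals=n_intervals,
                            boundary=(-2.0, 3.0), penalty_order=1)
        x = rng.uniform(-2.0, 3.0, 50)
        B = build_bspline_basis(x, bd)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12

    def test_few_distinct_values_reduce_intervals(self):
        x = np.repeat(np.arange(5.0), 10)
        bd = spline_def_for(x, "vaccinations", n_intervals=20)
        assert bd.n_intervals == 4


class TestDifferencePenalty:
    def test_first_order_hand_matrix(self):
        K = build_difference_penalty(4, 1).matrix
        expected = np.array([
            [1, -1, 0, 0], [-1, 2, -1, 0], [0, -1, 2, -1], [0, 0, -1, 1],
        ], dtype=float)
        assert np.allclose(K, expected)

    @pytest.mark.parametrize("n,order", [(5, 1), (8, 2), (10, 3)])
    def test_null_space_is_low_order_polynomials(self, n, order):
        pen = build_difference_penalty(n, order)
        assert pen.rank == n - order
        assert np.linalg.matrix_rank(pen.matrix, tol=1e-10) == n - order
        for deg in range(order):
            v = np.arange(1.0, n + 1.0) ** deg
            assert np.abs(pen.matrix @ v).max() < 1e-9
        # one degree higher is NOT annihilated
        v = np.arange(1.0, n + 1.0) ** order
        assert np.abs(pen.matrix @ v).max() > 1e-6

    def test_order_too_large_errors(self):
        with pytest.raises(ValueError):
            build_difference_penalty(3, 3)


class TestTensorBasis:
    def test_dimensions_and_partition_of_unity(self, rng):
        d1 = SplineBasisDef("a", 3, 10, (0, 1))
        d2 = SplineBasisDef("b", 3, 10, (0, 1))
        x1, x2 = rng.uniform(0, 1, (2, 40))
        B, K = build_tensor_basis(x1, x2, d1, d2)
        assert B.shape == (40, 169)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12
        assert K.dim == 169

    def test_penalty_is_kronecker_sum(self, rng):
        # assemble the Kronecker sum element-by-element on 3x3 marginals
        d1 = SplineBasisDef("a", 1, 2, (0, 1), penalty_order=1)
        d2 = SplineBasisDef("b", 1, 2, (0, 1), penalty_order=1)
        x = rng.uniform(0, 1, (2, 10))
        _, K = build_tensor_basis(x[0], x[1], d1, d2)
        K1 = build_difference_penalty(3, 1).matrix
        K2 = build_difference_penalty(3, 1).matrix
        expected = np.zeros((9, 9))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    for l in range(3):
                        expected[3 * i + j, 3 * k + l] = (
                            K1[i, k] * (j == l) + (i == k) * K2[j, l]
                        )
        assert np.allclose(K.matrix, expected)

    def test_length_mismatch(self):
        d = SplineBasisDef("a", 3, 4, (0, 1))
        with pytest.raises(ValueError):
            build_tensor_basis(np.zeros(3), np.zeros(4), d, d)


class TestMRFPenalty:
    def test_path_graph_hand_matrix(self):
        g = DistrictGraph(["a", "b", "c"], {("a", "b"), ("b", "c")})
        K = build_mrf_penalty(g).matrix
        assert np.allclose(K, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_row_sums_vanish(self, lattice5):
        graph, _ = lattice5
        K = build_mrf_penalty(graph).matrix
        assert np.abs(K.sum(axis=1)).max() < 1e-12

    def test_conditional_is_neighbour_average(self):
        # node a with neighbours b, c: mean of beta_a | beta_b=2, beta_c=4
        # is 3, variance tau^2 / 2; verified by conditioning a proper
        # approximation of the joint Gaussian with precision K/tau^2
        g = DistrictGraph(["a", "b", "c"], {("a", "b"), ("a", "c")})
        tau2 = 1.7
        K = build_mrf_penalty(g).matrix
        P = K / tau2 + 1e-9 * np.eye(3)
        # conditional of x0 | x1, x2 under precision P:
        # mean = -P00^-1 (P01 x1 + P02 x2), var = 1/P00
        mean = -(P[0, 1] * 2.0 + P[0, 2] * 4.0) / P[0, 0]
        var = 1.0 / P[0, 0]
        assert np.isclose(mean, 3.0, atol=1e-6)
        assert np.isclose(var, tau2 / 2.0, rtol=1e-6)

    @pytest.mark.parametrize("edges", [
        {("a", "b"), ("b", "c"), ("c", "d")},
        {("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")},
        {("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e")},
    ])
    def test_conditional_moments_any_graph(self, edges):
        nodes = sorted({n for e in edges for n in e})
        g = DistrictGraph(nodes, edges)
        tau2 = 0.8
        K = build_mrf_penalty(g).matrix
        P = K / tau2
        rng = np.random.default_rng(0)
        beta = rng.normal(size=len(nodes))
        for i, node in enumerate(nodes):
            nb = [g.index(m) for m in g.neighbours(node)]
            mean = -np.dot(P[i, nb], beta[nb]) / P[i, i]
            assert np.isclose(mean, np.mean(beta[nb]))
            assert np.isclose(1.0 / P[i, i], tau2 / len(nb))

    def test_islands_allowed_with_zero_row(self):
        g = DistrictGraph(["a", "b", "iso"], {("a", "b")})
        pen = build_mrf_penalty(g)
        assert np.allclose(pen.matrix[2], 0.0)
        assert g.islands == ["iso"]
        assert pen.rank_deficiency == 2  # two components

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DistrictGraph(["a", "b"], {("a", "a")})

    def test_graph_roundtrip(self, tmp_path, lattice5):
        graph, _ = lattice5
        write_district_graph(graph, tmp_path / "e.txt", tmp_path / "n.txt")
        back = read_district_graph(tmp_path / "e.txt", tmp_path / "n.txt")
        assert back.nodes == graph.nodes
        assert back.edges == graph.edges


class TestSumToZeroConstraint:
    def test_fitted_values_sum_to_zero(self, rng):
        B = rng.normal(size=(50, 8))
        pen = build_difference_penalty(8, 2)
        Bc, Kc, Z = apply_sum_to_zero_constraint(B, pen)
        assert Bc.shape == (50, 7)
        beta = rng.normal(size=7)
        assert abs((Bc @ beta).sum()) < 1e-10

    def test_constant_column_annihilated(self):
        B = np.ones((20, 1))
        pen = PenaltyMatrix(matrix=np.zeros((1, 1)), rank_deficiency=1)
        Bc, _, Z = apply_sum_to_zero_constraint(B, pen)
        assert Bc.shape[1] == 0

    def test_projector_idempotent(self, rng):
        B = rng.normal(size=(30, 6))
        pen = build_difference_penalty(6, 1)
        _, _, Z = apply_sum_to_zero_constraint(B, pen)
        # back-transform then re-constrain: projector P = Z Z' must be
        # idempotent and annihilate the constrained-out direction
        P = Z @ Z.T
        assert np.allclose(P @ P, P, atol=1e-10)
        c = B.sum(axis=0)
        assert np.abs(P @ c).max() < 1e-8

    def test_penalty_rank_deficiency_reduced(self, rng):
        # spline constraint removes the constant from the RW2 null space,
        # leaving only the linear direction
        bd = SplineBasisDef("x", 3, 8, (0, 1), penalty_order=2)
        B = build_bspline_basis(rng.uniform(0, 1, 100), bd)
        pen = build_difference_penalty(bd.n_basis, 2)
        _, Kc, _ = apply_sum_to_zero_constraint(B, pen)
        assert Kc.rank_deficiency == 1


class TestEffectCode:
    def test_two_levels(self):
        X, cols = effect_code(np.array(["boy", "girl", "boy"]), reference_level="girl")
        assert cols == ["boy"]
        assert np.allclose(X[:, 0], [1, -1, 1])

    def test_balanced_columns_sum_to_zero(self):
        f = np.repeat(["a", "b", "c"], 4)
        X, cols = effect_code(f)
        assert len(cols) == 2
        assert np.allclose(X.sum(axis=0), 0.0)

    def test_single_level_errors(self):
        with pytest.raises(ValueError):
            effect_code(np.array(["a", "a"]))

    def test_absent_reference_errors(self):
        with pytest.raises(ValueError):
            effect_code(np.array(["a", "b"]), reference_level="z")

    def test_default_reference_is_last_sorted(self):
        _, cols = effect_code(np.array(["urban", "rural", "urban"]))
        assert cols == ["rural"]  # reference = 'urban' (last in sort)
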