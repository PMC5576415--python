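import numpy as np
import pytest
from scipy.optimize import minimize

from adwave.twinsvm import (
    TSVMModel,
    TSVMProblem,
    solve_box_qp,
    tsvm_decision_distances,
    tsvm_fit,
    tsvm_grid_search,
    tsvm_predict,
)


def primal_plane_oracle(A, B, C, eps_rel=1e-6):
    """Independent generic-QP solve of the proximal-plane primal (SLSQP).

    min 1/2||A u||^2 + eps/2 ||u||^2 + C 1'xi  s.t. -(B u) + xi >= 1, xi >= 0
    with u = [w; b] and the same relative ridge as the dual route.
    """
    n1, p = A.shape
    n2 = B.shape[0]
    H = np.hstack([A, np.ones((n1, 1))])
    G = np.hstack([B, np.ones((n2, 1))])
    M = H.T @ H
    eps = eps_rel * (np.trace(M) / M.shape[0] + 1.0)

    def obj(v):
        u, xi = v[: p + 1], v[p + 1 :]
        return 0.5 * np.sum((H @ u) ** 2) + 0.5 * eps * np.sum(u ** 2) + C * np.sum(xi)

    def grad(v):
        u = v[: p + 1]
        return np.concatenate([H.T @ (H @ u) + eps * u, np.full(n2, C)])

    cons = [
        {"type": "ineq", "fun": lambda v: -(G @ v[: p + 1]) + v[p + 1 :] - 1.0,
         "jac": lambda v: np.hstack([-G, np.eye(n2)])},
        {"type": "ineq", "fun": lambda v: v[p + 1 :],
         "jac": lambda v: np.hstack([np.zeros((n2, p + 1)), np.eye(n2)])},
    ]
    v0 = np.zeros(p + 1 + n2)
    v0[p + 1 :] = 1.0
    res = minimize(obj, v0, jac=grad, constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-14})
    return res.x[: p], float(res.x[p])


@pytest.fixture
def parallel_rows_fixture():
    X1 = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    X2 = np.array([[0.0, 2.0], [1.0, 2.0], [2.0, 2.0]])
    return X1, X2


class TestFit:
    def test_planes_pass_through_their_classes(self, parallel_rows_fixture):
        X1, X2 = parallel_rows_fixture
        m = tsvm_fit(TSVMProblem(X1, X2, C1=1.0, C2=1.0))
        assert np.max(np.abs(X1 @ m.w1 + m.b1)) < 1e-4  # plane 1 ~ y = 0
        assert np.max(np.abs(X2 @ m.w2 + m.b2)) < 1e-4  # plane 2 ~ y = 2
        assert m.kkt_residual < 1e-6

    def test_matches_primal_qp_oracle_on_small_instances(self, rng):
        for _ in range(6):
            n1 = int(rng.integers(3, 11))
            n2 = int(rng.integers(3, 10))  # n1 + n2 <= 20
            p = int(rng.integers(2, 5))
            X1 = rng.standard_normal((n1, p))
            X2 = rng.standard_normal((n2, p)) + rng.uniform(0.5, 2.5)
            C = float(rng.choice([0.25, 1.0, 4.0]))
            m = tsvm_fit(TSVMProblem(X1, X2, C1=C, C2=C))
            w_o, b_o = primal_plane_oracle(X1, X2, C)
            u = np.concatenate([m.w1, [m.b1]])
            uo = np.concatenate([w_o, [b_o]])
            assert np.linalg.norm(u - uo) <= 1e-4 * max(1.0, np.linalg.norm(uo))

    def test_dual_primal_objective_agreement(self, rng):
        X1 = rng.standard_normal((8, 3))
        X2 = rng.standard_normal((7, 3)) + 1.5
        prob = TSVMProblem(X1, X2, C1=2.0, C2=2.0)
        m = tsvm_fit(prob)
        H = np.hstack([X1, np.ones((8, 1))])
        G = np.hstack([X2, np.ones((7, 1))])
        M = H.T @ H
        eps = prob.epsilon * (np.trace(M) / M.shape[0] + 1.0)
        u = np.concatenate([m.w1, [m.b1]])
        xi = np.maximum(0.0, 1.0 + G @ u)
        primal = 0.5 * np.sum((H @ u) ** 2) + 0.5 * eps * u @ u + prob.C1 * xi.sum()
        alpha = m.duals["alpha"]
        Q = G @ np.linalg.solve(M + eps * np.eye(4), G.T)
        dual = alpha.sum() - 0.5 * alpha @ Q @ alpha
        assert abs(primal - dual) < 1e-5 * max(1.0, abs(primal))

    def test_duplicating_points_leaves_plane_unchanged(self, parallel_rows_fixture):
        X1, X2 = parallel_rows_fixture
        m1 = tsvm_fit(TSVMProblem(X1, X2))
        m2 = tsvm_fit(TSVMProblem(np.vstack([X1, X1]), X2))
        # geometry is the same point set; compare normalized plane 1
        u1 = np.concatenate([m1.w1, [m1.b1]])
        u2 = np.concatenate([m2.w1, [m2.b1]])
        assert np.max(np.abs(u1 / np.linalg.norm(m1.w1) - u2 / np.linalg.norm(m2.w1))) < 1e-3

    def test_label_swap_exchanges_planes(self, rng):
        X1 = rng.standard_normal((6, 3))
        X2 = rng.standard_normal((5, 3)) + 1.0
        m = tsvm_fit(TSVMProblem(X1, X2))
        ms = tsvm_fit(TSVMProblem(X2, X1))
        assert np.max(np.abs(m.w1 - ms.w2)) < 1e-8
        assert abs(m.b1 - ms.b2) < 1e-8
        assert np.max(np.abs(m.w2 - ms.w1)) < 1e-8

    def test_invalid_problems_rejected(self):
        X = np.zeros((2, 2))
        with pytest.raises(ValueError):
            TSVMProblem(X, np.zeros((0, 2)))
        with pytest.raises(ValueError):
            TSVMProblem(X, X, C1=-1.0)
        with pytest.raises(ValueError):
            TSVMProblem(X, X, epsilon=0.0)


class TestPredict:
    def test_nearest_plane_geometry(self, parallel_rows_fixture):
        m = tsvm_fit(TSVMProblem(*parallel_rows_fixture))
        assert tsvm_predict(m, [[1.0, -0.5]]) == [1]
        assert tsvm_predict(m, [[1.0, 2.4]]) == [-1]
        d1, d2 = tsvm_decision_distances(m, [[1.0, -0.5]])
        assert d1[0] == pytest.approx(0.5, abs=1e-3)
        assert d2[0] == pytest.approx(2.5, abs=1e-3)

    def test_exact_tie_goes_to_class_one(self):
        m = TSVMModel(np.array([0.0, 1.0]), 0.0, np.array([0.0, 1.0]), -2.0)
        assert tsvm_predict(m, [[0.0, 1.0]]) == [1]  # equidistant from y=0, y=2

    def test_separable_training_data_fully_recovered(self, parallel_rows_fixture):
        X1, X2 = parallel_rows_fixture
        m = tsvm_fit(TSVMProblem(X1, X2))
        X = np.vstack([X1, X2])
        y = np.array([1] * 3 + [-1] * 3)
        assert np.array_equal(tsvm_predict(m, X), y)

    def test_zero_normal_is_degenerate(self):
        m = TSVMModel(np.zeros(2), 0.0, np.array([0.0, 1.0]), -2.0)
        with pytest.raises(ValueError, match="degenerate"):
            tsvm_predict(m, [[0.0, 0.0]])

    @pytest.mark.parametrize("s", [0.1, 3.0, 50.0])
    def test_scale_equivariance_of_predictions(self, rng, s):
        X1 = rng.standard_normal((10, 2))
        X2 = rng.standard_normal((10, 2)) + 2.0
        Xt = rng.standard_normal((20, 2)) + 1.0
        m = tsvm_fit(TSVMProblem(X1, X2))
        ms = tsvm_fit(TSVMProblem(s * X1, s * X2))
        assert np.array_equal(tsvm_predict(m, Xt), tsvm_predict(ms, s * Xt))
        d1, d2 = tsvm_decision_distances(m, Xt)
        s1, s2 = tsvm_decision_distances(ms, s * Xt)
        # distances scale by s up to the (bias-penalizing) relative ridge
        assert np.allclose(s1, s * d1, rtol=1e-2)


class TestBoxQP:
    def test_interior_solution_matches_linear_solve(self, rng):
        A = rng.standard_normal((6, 4))
        Q = A.T @ A + 0.5 * np.eye(4)
        a_true = rng.uniform(0.5, 2.0, size=4)  # strictly inside the box
        q = Q @ a_true
        a, resid = solve_box_qp(Q, q, ub=100.0)
        assert resid < 1e-8
        assert np.allclose(a, a_true, atol=1e-7)

    def test_kkt_residual_reported(self, rng):
        A = rng.standard_normal((5, 5))
        Q = A @ A.T
        a, resid = solve_box_qp(Q, np.ones(5), ub=1.0)
        g = Q @ a - np.ones(5)
        assert resid == pytest.approx(np.max(np.abs(a - np.clip(a - g, 0, 1))), abs=1e-12)
        assert resid < 1e-8


class TestGridSearch:
    def test_single_value_grid_returns_it(self, rng):
        X1 = rng.standard_normal((9, 2))
        X2 = rng.standard_normal((9, 2)) + 3.0
        X = np.vstack([X1, X2])
        y = np.array([1] * 9 + [-1] * 9)
        assert tsvm_grid_search(X, y, [0.5]) == (0.5, 0.5)

    def test_separable_data_picks_smallest_penalties(self, rng):
        X1 = rng.standard_normal((9, 2))
        X2 = rng.standard_normal((9, 2)) + 6.0
        X = np.vstack([X1, X2])
        y = np.array([1] * 9 + [-1] * 9)
        grid = [0.25, 1.0, 4.0]
        assert tsvm_grid_search(X, y, grid) == (0.25, 0.25)

    def test_selected_pair_is_exhaustively_optimal(self, rng):
        from itertools import product

        from adwave.twinsvm import _inner_cv_accuracy

        X1 = rng.standard_normal((12, 2))
        X2 = rng.standard_normal((12, 2)) + 1.0  # noisy overlap
        X = np.vstack([X1, X2])
        y = np.array([1] * 12 + [-1] * 12)
        grid = [0.5, 2.0]
        C1, C2 = tsvm_grid_search(X, y, grid, seed=3)
        best = _inner_cv_accuracy(X, y, C1, C2, 1e-6, 3, 3)
        for a, b in product(grid, grid):
            assert best >= _inner_cv_accuracy(X, y, a, b, 1e-6, 3, 3)
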