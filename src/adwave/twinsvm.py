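"""Linear Twin SVM: two nonparallel hyperplanes, one close to each class.

The classifier solves two small quadratic programs.  With H = [X1 e],
G = [X2 e] (a trailing column of ones absorbing the bias), plane 1

    min_{w1,b1,xi}  1/2 ||X1 w1 + e b1||^2 + C1 e' xi
    s.t.            -(X2 w1 + e b1) + xi >= e,   xi >= 0

is solved through its Lagrange dual

    max_alpha  e' alpha - 1/2 alpha' G (H'H + eps I)^{-1} G' alpha,
    0 <= alpha <= C1,

after which [w1; b1] = -(H'H + eps I)^{-1} G' alpha; plane 2 is the same
problem with the class roles swapped (and [w2; b2] = +(G'G + eps I)^{-1} H' beta).
The ridge eps (relative to the matrix trace) is required because H'H is rank
deficient whenever features >= samples.  A sample is assigned to the class
whose hyperplane is nearer in perpendicular distance |w'x + b| / ||w||,
ties going to class 1 (the patient class).

The dual box-constrained QP is solved by projected Newton iterations on the
free set; the normative contract is the KKT residual (projected-gradient
infinity norm) below 1e-6, not the particular algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "TSVMProblem",
    "TSVMModel",
    "solve_box_qp",
    "tsvm_fit",
    "tsvm_predict",
    "tsvm_decision_distances",
    "tsvm_grid_search",
]


@dataclass
class TSVMProblem:
    """Training data and penalties; X1 = patient class, X2 = control class."""

    X1: np.ndarray
    X2: np.ndarray
    C1: float = 1.0
    C2: float = 1.0
    epsilon: float = 1e-6  # ridge, relative to trace of the Gram matrix

    def __post_init__(self) -> None:
        self.X1 = np.atleast_2d(np.asarray(self.X1, dtype=float))
        self.X2 = np.atleast_2d(np.asarray(self.X2, dtype=float))
        if self.X1.shape[0] == 0 or self.X2.shape[0] == 0:
            raise ValueError("both classes must be nonempty")
        if self.X1.shape[1] != self.X2.shape[1]:
            raise ValueError("X1 and X2 must have the same feature count")
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("penalties C1, C2 must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class TSVMModel:
    w1: np.ndarray
    b1: float
    w2: np.ndarray
    b2: float
    duals: dict = field(default_factory=dict)
    kkt_residual: float = np.nan
    C1: float = 1.0
    C2: float = 1.0
    epsilon: float = 1e-6

    def to_json(self) -> str:
        return json.dumps(
            {
                "w1": self.w1.tolist(),
                "b1": self.b1,
                "w2": self.w2.tolist(),
                "b2": self.b2,
                "C1": self.C1,
                "C2": self.C2,
                "epsilon": self.epsilon,
                "kkt_residual": self.kkt_residual,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TSVMModel":
        d = json.loads(text)
        return cls(
            np.array(d["w1"]), d["b1"], np.array(d["w2"]), d["b2"],
            kkt_residual=d["kkt_residual"], C1=d["C1"], C2=d["C2"],
            epsilon=d["epsilon"],
        )


def solve_box_qp(
    Q: np.ndarray,
    q: np.ndarray,
    ub: float,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Minimize 1/2 a'Qa - q'a subject to 0 <= a <= ub (Q symmetric PSD).

    Projected Newton with active-set identification; returns the solution and
    the projected-gradient infinity norm.
    """
    n = len(q)
    a = np.full(n, min(ub, 1.0) * 0.5)
    jitter = 1e-12 * (np.trace(Q) / n + 1.0)
    obj = 0.5 * a @ Q @ a - q @ a
    for _ in range(max_iter):
        g = Q @ a - q
        lo_active = (a <= 0) & (g >= 0)
        hi_active = (a >= ub) & (g <= 0)
        free = ~(lo_active | hi_active)
        resid = float(np.max(np.abs(a - np.clip(a - g, 0.0, ub)), initial=0.0))
        if resid < tol:
            break
        if not np.any(free):
            break
        F = np.flatnonzero(free)
        QFF = Q[np.ix_(F, F)] + jitter * np.eye(len(F))
        try:
            d = np.linalg.solve(QFF, -g[F])
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(QFF, -g[F], rcond=None)[0]
        step = np.zeros(n)
        step[F] = d
        t = 1.0
        for _ls in range(60):
            a_new = np.clip(a + t * step, 0.0, ub)
            obj_new = 0.5 * a_new @ Q @ a_new - q @ a_new
            if obj_new <= obj + 1e-14 * abs(obj):
                break
            t *= 0.5
        if np.allclose(a_new, a):
            # fall back to a projected-gradient step to escape a stalled face
            t = 1.0 / (np.linalg.norm(Q, ord=np.inf) + 1.0)
            a_new = np.clip(a - t * g, 0.0, ub)
            obj_new = 0.5 * a_new @ Q @ a_new - q @ a_new
        a, obj = a_new, obj_new
    g = Q @ a - q
    resid = float(np.max(np.abs(a - np.clip(a - g, 0.0, ub)), initial=0.0))
    return a, resid


def _solve_plane(A: np.ndarray, B: np.ndarray, C: float, eps_rel: float):
    """Plane proximal to A, pushed unit distance from B.

    Returns (w, b, dual, kkt_residual, M_inv_Bt) for
    min 1/2||A u||^2 + C e'xi, s.t. -(B u) + xi >= e (u = [w; b]).
    """
    H = np.hstack([A, np.ones((A.shape[0], 1))])
    G = np.hstack([B, np.ones((B.shape[0], 1))])
    M = H.T @ H
    eps = eps_rel * (np.trace(M) / M.shape[0] + 1.0)
    M += eps * np.eye(M.shape[0])
    MinvGt = np.linalg.solve(M, G.T)
    Q = G @ MinvGt
    Q = 0.5 * (Q + Q.T)
    alpha, resid = solve_box_qp(Q, np.ones(G.shape[0]), C)
    u = -MinvGt @ alpha
    return u[:-1], float(u[-1]), alpha, resid


def tsvm_fit(problem: TSVMProblem, kkt_tol: float = 1e-6) -> TSVMModel:
    """Fit both hyperplanes via the dual QPs.

    Raises ``RuntimeError`` carrying the achieved residual if the solver
    fails to meet the KKT tolerance.
    """
    # plane 2 is plane 1 with the class roles swapped (the printed form keeps
    # the minus sign in both constraints, so label swap exchanges the planes
    # exactly; only |w.x + b| enters prediction, so orientation is immaterial)
    w1, b1, alpha, r1 = _solve_plane(problem.X1, problem.X2, problem.C1, problem.epsilon)
    w2, b2, gamma, r2 = _solve_plane(problem.X2, problem.X1, problem.C2, problem.epsilon)
    resid = max(r1, r2)
    if not np.isfinite(resid) or resid > kkt_tol:
        raise RuntimeError(
            f"TSVM dual QP failed to converge: KKT residual {resid:.3e} > {kkt_tol:.0e}"
        )
    return TSVMModel(
        w1, b1, w2, b2,
        duals={"alpha": alpha, "gamma": gamma},
        kkt_residual=resid,
        C1=problem.C1, C2=problem.C2, epsilon=problem.epsilon,
    )


def tsvm_decision_distances(model: TSVMModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Perpendicular distances |w_k . x + b_k| / ||w_k|| to the two planes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n1, n2 = np.linalg.norm(model.w1), np.linalg.norm(model.w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate model: a hyperplane has zero normal vector")
    d1 = np.abs(X @ model.w1 + model.b1) / n1
    d2 = np.abs(X @ model.w2 + model.b2) / n2
    return d1, d2


def tsvm_predict(model: TSVMModel, X) -> np.ndarray:
    """+1 (patient) where plane 1 is nearer, -1 otherwise; ties go to class 1."""
    d1, d2 = tsvm_decision_distances(model, X)
    return np.where(d1 <= d2, 1, -1)


def _inner_cv_accuracy(X, y, C1, C2, epsilon, k, seed) -> float:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = total = 0
    for tr, te in skf.split(X, y):
        model = tsvm_fit(TSVMProblem(X[tr][y[tr] == 1], X[tr][y[tr] == -1],
                                     C1=C1, C2=C2, epsilon=epsilon))
        correct += int(np.sum(tsvm_predict(model, X[te]) == y[te]))
        total += len(te)
    return correct / total


def tsvm_grid_search(
    Xtrain,
    labels,
    C_grid,
    epsilon: float = 1e-6,
    k: int = 3,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C1, C2) maximizing inner stratified-CV accuracy.

    The grid is scanned in ascending (C1, C2) order and only strict
    improvements are kept, so ties resolve toward the smaller penalties.
    """
    grid = sorted(float(c) for c in C_grid)
    if not grid or grid[0] <= 0:
        raise ValueError("C_grid must contain positive values")
    X = np.asarray(Xtrain, dtype=float)
    y = np.asarray(labels)
    best, best_acc = None, -1.0
    for C1, C2 in product(grid, grid):
        acc = _inner_cv_accuracy(X, y, C1, C2, epsilon, k, seed)
        if acc > best_acc:
            best, best_acc = (C1, C2), acc
    return best
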