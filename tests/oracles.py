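"""Independent reference computations used to check the package's results.

Each oracle takes a deliberately different route from the implementation it
checks: contingency-table phi instead of vector algebra, a constrained
optimizer on the primal QP instead of the SMO dual, two-pass summation
instead of numpy's moment routines, and exhaustive pair counting for AUC.
"""

import math

import numpy as np
from scipy.optimize import minimize


def phi_from_contingency(a, b) -> float:
    """Phi coefficient of two binary vectors from their 2x2 table:
    (n11*n00 - n10*n01) / sqrt(n1+ * n0+ * n+1 * n+0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    denom = math.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / denom


def svr_primal_solve(X: np.ndarray, y: np.ndarray, C: float, eps: float):
    """Solve the soft-tube epsilon-SVR primal directly:

        min 1/2 ||w||^2 + C sum(xi + xihat)
        s.t. (Xw + b) - y <= eps + xi,  y - (Xw + b) <= eps + xihat,
             xi >= 0, xihat >= 0

    with sequential least-squares programming (whose quadratic subproblem
    is this problem itself, so it converges to the exact optimum).
    Returns (w, b, objective).
    """
    n, p = X.shape
    nv = p + 1 + 2 * n  # w, b, xi, xihat

    def obj(z):
        w, xi, xih = z[:p], z[p + 1 : p + 1 + n], z[p + 1 + n :]
        return 0.5 * float(w @ w) + C * float(xi.sum() + xih.sum())

    def grad(z):
        g = np.zeros(nv)
        g[:p] = z[:p]
        g[p + 1 :] = C
        return g

    # inequality rows (A z >= lb): eps + xi_i - (f(x_i) - y_i) >= 0 and
    # eps + xihat_i - (y_i - f(x_i)) >= 0
    A = np.zeros((2 * n, nv))
    A[:n, :p] = -X
    A[:n, p] = -1.0
    A[:n, p + 1 : p + 1 + n] = np.eye(n)
    A[n:, :p] = X
    A[n:, p] = 1.0
    A[n:, p + 1 + n :] = np.eye(n)
    lb = np.concatenate([-(y + eps), y - eps])

    res = minimize(
        obj,
        x0=np.zeros(nv),
        jac=grad,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda z: A @ z - lb, "jac": lambda z: A}],
        bounds=[(None, None)] * (p + 1) + [(0.0, None)] * (2 * n),
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    return res.x[:p], float(res.x[p]), float(res.fun)


def svr_primal_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                         C: float, eps: float) -> float:
    """Primal objective of a given (w, b) with optimal slacks."""
    f = X @ w + b
    xi = np.maximum(0.0, f - y - eps)
    xih = np.maximum(0.0, y - f - eps)
    return 0.5 * float(w @ w) + C * float(xi.sum() + xih.sum())


def two_pass_sample_sd(values) -> float:
    """Textbook two-pass sample standard deviation (divisor n-1)."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    return math.sqrt(ss / (n - 1))


def brute_force_auc(values, labels) -> float:
    """Exhaustive positive x negative pair count with half credit for ties."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
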