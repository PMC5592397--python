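"""Independent brute-force minimizers used as test oracles.

Every prox operator in the package claims to minimize an objective of the
form  g(z) + 1/(2 tau) ||z - x||^2.  The helpers here minimize those
objectives by generic constrained optimization (l1 terms rewritten with
auxiliary slack variables and linear constraints, solved by SLSQP) or by
derivative-free search, never by the closed forms or primal-dual schemes the
implementation itself uses.
"""

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def scalar_l1_prox(c: float, tau: float) -> float:
    """Numeric minimizer of tau*|m| + 0.5*(m - c)^2 over m >= 0 for c >= 0."""
    res = minimize_scalar(lambda m: tau * m + 0.5 * (m - c) ** 2,
                          bounds=(0.0, max(c, 1.0) + tau + 1.0),
                          method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def l1_analysis_prox(w_matrix: np.ndarray, x: np.ndarray, weight: float,
                     tol: float = 1e-12) -> np.ndarray:
    """Minimize weight*||W z||_1 + 0.5*||z - x||^2 for real x and real W.

    Slack reformulation: min over (z, s) of weight*sum(s) + 0.5||z - x||^2
    subject to -s <= W z <= s, solved with SLSQP.
    """
    n = x.size
    m = w_matrix.shape[0]

    def objective(zs):
        z, s = zs[:n], zs[n:]
        return weight * s.sum() + 0.5 * np.sum((z - x) ** 2)

    def jac(zs):
        z, s = zs[:n], zs[n:]
        return np.concatenate([z - x, np.full(m, weight)])

    cons = [
        {"type": "ineq", "fun": lambda zs: zs[n:] - w_matrix @ zs[:n],
         "jac": lambda zs: np.hstack([-w_matrix, np.eye(m)])},
        {"type": "ineq", "fun": lambda zs: zs[n:] + w_matrix @ zs[:n],
         "jac": lambda zs: np.hstack([w_matrix, np.eye(m)])},
    ]
    z0 = np.concatenate([x, np.abs(w_matrix @ x) + 1.0])
    res = minimize(objective, z0, jac=jac, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": tol})
    return res.x[:n]


def tv_prox_bruteforce(x: np.ndarray, weight: float) -> np.ndarray:
    """Brute-force temporal TV prox on a real 1-D series."""
    n = x.size
    d1 = np.diff(np.eye(n), axis=0)  # (n-1, n) forward differences
    return l1_analysis_prox(d1, x, weight)


def tgv_prox_bruteforce(x: np.ndarray, alpha1: float, alpha0: float,
                        v_boundary: str = "neumann") -> np.ndarray:
    """Brute-force temporal TGV2 prox on a real 1-D series.

    Joint variables (z, v, s1, s2) with the same discrete objective as the
    package: alpha1*||D z - v||_1 + alpha0*||D2 v||_1 + 0.5*||z - x||^2,
    D2 Neumann (interior second differences) or Dirichlet (zero-extended).
    """
    n = x.size
    nv = n - 1
    d1 = np.diff(np.eye(n), axis=0)                    # (n-1, n)
    if v_boundary == "neumann":
        d2 = np.diff(np.eye(nv), axis=0)               # (n-2, n-1)
    else:
        d2 = np.vstack([np.diff(np.eye(nv), axis=0), np.zeros(nv)])
        d2[-1, -1] = -1.0                              # (n-1, n-1)
    m1, m2 = d1.shape[0], d2.shape[0]
    # unknown layout: [z (n), v (nv), s1 (m1), s2 (m2)]
    off_v, off_s1, off_s2 = n, n + nv, n + nv + m1
    total = n + nv + m1 + m2

    def objective(u):
        return (alpha1 * u[off_s1:off_s2].sum() + alpha0 * u[off_s2:].sum()
                + 0.5 * np.sum((u[:n] - x) ** 2))

    def jac(u):
        g = np.zeros(total)
        g[:n] = u[:n] - x
        g[off_s1:off_s2] = alpha1
        g[off_s2:] = alpha0
        return g

    a_r1 = np.zeros((m1, total))
    a_r1[:, :n] = d1
    a_r1[:, off_v:off_s1] = -np.eye(nv)
    a_r2 = np.zeros((m2, total))
    a_r2[:, off_v:off_s1] = d2
    e1 = np.zeros((m1, total)); e1[:, off_s1:off_s2] = np.eye(m1)
    e2 = np.zeros((m2, total)); e2[:, off_s2:] = np.eye(m2)
    cons = [
        {"type": "ineq", "fun": lambda u: e1 @ u - a_r1 @ u, "jac": lambda u: e1 - a_r1},
        {"type": "ineq", "fun": lambda u: e1 @ u + a_r1 @ u, "jac": lambda u: e1 + a_r1},
        {"type": "ineq", "fun": lambda u: e2 @ u - a_r2 @ u, "jac": lambda u: e2 - a_r2},
        {"type": "ineq", "fun": lambda u: e2 @ u + a_r2 @ u, "jac": lambda u: e2 + a_r2},
    ]
    u0 = np.zeros(total)
    u0[:n] = x
    u0[off_s1:off_s2] = np.abs(d1 @ x) + 1.0
    u0[off_s2:] = 1.0
    res = minimize(objective, u0, jac=jac, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-12})
    return res.x[:n]


def nuclear_prox_bruteforce(x_mat: np.ndarray, tau: float) -> np.ndarray:
    """Derivative-free minimization of tau*||Z||_* + 0.5*||Z - X||_F^2.

    Multi-start Powell polished by Nelder-Mead; the objective is 1-strongly
    convex, so a solution with objective within eps of optimal lies within
    sqrt(2*eps) of the unique minimizer. Individual starts can stall on the
    nonsmooth rank-deficient set, hence the restarts.
    """
    shape = x_mat.shape

    def objective(zflat):
        z = zflat.reshape(shape)
        return (tau * np.linalg.svd(z, compute_uv=False).sum()
                + 0.5 * np.sum((z - x_mat) ** 2))

    best = None
    for start in (x_mat, 0.5 * x_mat, np.zeros_like(x_mat)):
        res = minimize(objective, start.ravel(), method="Powell",
                       options={"maxiter": 20000, "xtol": 1e-12, "ftol": 1e-14})
        res = minimize(objective, res.x, method="Nelder-Mead",
                       options={"maxiter": 40000, "xatol": 1e-12, "fatol": 1e-15})
        if best is None or res.fun < best.fun:
            best = res
    return best.x.reshape(shape)


def nuclear_prox_distance_bound(x_mat: np.ndarray, tau: float,
                                z: np.ndarray) -> float:
    """Certified distance from ``z`` to the true minimizer of
    tau*||Z||_* + 0.5*||Z - X||_F^2, via convex duality.

    For any W with spectral norm <= tau, the dual value
    <W, X> - 0.5*||W||_F^2 lower-bounds the optimum; with W = X - z the
    duality gap bounds ||z - Z*||^2 / 2 by 1-strong convexity. Returns inf
    if W is dual-infeasible.
    """
    w = x_mat - z
    if np.linalg.norm(w, 2) > tau * (1 + 1e-10):
        return float("inf")
    primal = (tau * np.linalg.svd(z, compute_uv=False).sum()
              + 0.5 * np.sum((z - x_mat) ** 2))
    dual = np.sum(w * x_mat) - 0.5 * np.sum(w * w)
    gap = max(primal - dual, 0.0)
    return float(np.sqrt(2.0 * gap))


def lasso_bruteforce(q: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Minimize 0.5*||Q x - b||^2 + alpha*||x||_1 by slack reformulation."""
    n = q.shape[1]

    def objective(zs):
        z, s = zs[:n], zs[n:]
        r = q @ z - b
        return 0.5 * r @ r + alpha * s.sum()

    def jac(zs):
        z = zs[:n]
        return np.concatenate([q.T @ (q @ z - b), np.full(n, alpha)])

    eye = np.eye(n)
    cons = [
        {"type": "ineq", "fun": lambda zs: zs[n:] - zs[:n],
         "jac": lambda zs: np.hstack([-eye, eye])},
        {"type": "ineq", "fun": lambda zs: zs[n:] + zs[:n],
         "jac": lambda zs: np.hstack([eye, eye])},
    ]
    z0 = np.zeros(2 * n)
    z0[n:] = 1.0
    res = minimize(objective, z0, jac=jac, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x[:n]
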