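"""Dense convex quadratic programming.

Solves  min 1/2 x^T P x + q^T x  subject to  G x <= h  with a primal-dual
interior-point method (Mehrotra predictor-corrector on the perturbed KKT
system).  P must be positive semidefinite; a small diagonal regularization
keeps the Newton systems well posed when P is singular on the feasible set.

This is the workhorse behind the repulsive-potential fit, whose shape
constraints (monotone decreasing, convex) are linear inequalities on a dense
distance grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
from scipy.linalg import cho_factor, cho_solve, LinAlgError


class QPError(RuntimeError):
    pass


@dataclass
class QPResult:
    x: np.ndarray
    z: np.ndarray               # inequality multipliers
    objective: float
    gap: float
    n_iterations: int
    converged: bool


def solve_qp(P, q, G=None, h=None, tol: float = 1e-10, max_iter: int = 60,
             ridge: float = 0.0, x0=None) -> QPResult:
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(q)
    if ridge:
        P = P + ridge * np.eye(n)

    def objective(x):
        return float(0.5 * x @ P @ x + q @ x)

    if G is None or G.shape[0] == 0:
        try:
            x = np.linalg.solve(P, -q)
        except np.linalg.LinAlgError:
            x, *_ = np.linalg.lstsq(P, -q, rcond=None)
        return QPResult(x=x, z=np.zeros(0), objective=objective(x), gap=0.0,
                        n_iterations=0, converged=True)

    is_sparse = sparse.issparse(G)
    if not is_sparse:
        G = np.asarray(G, dtype=float)
    h = np.asarray(h, dtype=float)
    m = len(h)

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    s = np.maximum(h - G @ x, 1.0)
    z = np.ones(m)

    def kkt_solve(dia, rx, rs_over_s):
        # (P + G^T diag(z/s) G) dx = -rx - G^T rs_over_s
        if is_sparse:
            M = P + np.asarray((G.multiply(dia[:, None]).T @ G).todense())
        else:
            M = P + (G.T * dia) @ G
        rhs = -rx - G.T @ rs_over_s
        try:
            c = cho_factor(M + 1e-13 * np.trace(M) / n * np.eye(n))
            return cho_solve(c, rhs)
        except LinAlgError:
            return np.linalg.lstsq(M, rhs, rcond=None)[0]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rx = P @ x + q + G.T @ z          # dual residual
        rp = G @ x + s - h                # primal residual
        mu = s @ z / m
        if (np.linalg.norm(rx) < tol * (1 + np.linalg.norm(q))
                and np.linalg.norm(rp) < tol * (1 + np.linalg.norm(h))
                and mu < tol):
            converged = True
            break

        dia = z / s
        # affine (predictor) step: complementarity residual r_c = s.z
        rs_aff = dia * rp - z             # (z r_p - r_c)/s
        dx_aff = kkt_solve(dia, rx, rs_aff)
        ds_aff = -rp - G @ dx_aff
        dz_aff = -z - dia * ds_aff

        a_p = _max_step(s, ds_aff)
        a_d = _max_step(z, dz_aff)
        mu_aff = ((s + a_p * ds_aff) @ (z + a_d * dz_aff)) / m
        sigma = (mu_aff / mu) ** 3 if mu > 0 else 0.0

        # corrector
        rs_cent = (s * z + ds_aff * dz_aff - sigma * mu) / s
        dx = kkt_solve(dia, rx, dia * rp - rs_cent)
        ds = -rp - G @ dx
        dz = -rs_cent - dia * ds

        a_p = 0.99 * _max_step(s, ds)
        a_d = 0.99 * _max_step(z, dz)
        a = min(a_p, a_d)
        x = x + a * dx
        s = s + a * ds
        z = z + a * dz
    else:
        it = max_iter

    gap = float(s @ z / m)
    if not converged and gap > 1e-6:
        raise QPError(f"interior-point solver did not converge: gap {gap:.3e}, "
                      f"dual residual {np.linalg.norm(P @ x + q + G.T @ z):.3e}")
    return QPResult(x=x, z=z, objective=objective(x), gap=gap,
                    n_iterations=it, converged=converged)


def _max_step(v, dv):
    neg = dv < 0
    if not np.any(neg):
        return 1.0
    return min(1.0, float(np.min(-v[neg] / dv[neg])))
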