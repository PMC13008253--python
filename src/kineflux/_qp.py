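"""Convex quadratic programming by ADMM for the flux-fitting subproblem.

Solves

    min  1/2 x' H x + c' x   s.t.  S x = 0,  lb <= x <= ub

with diagonal positive-semidefinite H (the flux-deviation quadratic plus the
linear total-flux term).  The operator splitting alternates an
equality-constrained ridge step (one sparse KKT factorization, reused across
iterations) with a box projection — the standard consensus ADMM scheme.  The
returned iterate satisfies ``S x = 0`` to the accuracy of the KKT solve and
the bounds to the primal tolerance.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["QPResult", "solve_box_qp"]


class QPResult:
    def __init__(self, x, iterations, converged, primal_residual, dual_residual):
        self.x = x
        self.iterations = iterations
        self.converged = converged
        self.primal_residual = primal_residual
        self.dual_residual = dual_residual


def _factor(H_diag, S, rho):
    n = len(H_diag)
    m = S.shape[0]
    K = sp.bmat(
        [[sp.diags(H_diag + rho), S.T], [S, None]], format="csc"
    )
    # the (2,2) block is absent (exact equality constraint); K is symmetric
    # quasi-definite after the rho shift, LU handles it reliably at this scale
    return spla.splu(K, permc_spec="COLAMD")


def solve_box_qp(
    H_diag: np.ndarray,
    c: np.ndarray,
    S: sp.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    x0: np.ndarray | None = None,
    rho: float = 1.0,
    eps_abs: float = 1e-11,
    eps_rel: float = 1e-11,
    max_iter: int = 100_000,
    check_every: int = 25,
) -> QPResult:
    """ADMM with adaptive step parameter; see module docstring."""
    n = len(H_diag)
    S = sp.csc_matrix(S)
    m = S.shape[0]
    z = np.clip(x0 if x0 is not None else np.zeros(n), lb, ub)
    u = np.zeros(n)
    lu = _factor(H_diag, S, rho)
    rhs = np.zeros(n + m)
    x = z.copy()
    r_p = r_d = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rhs[:n] = rho * (z - u) - c
        sol = lu.solve(rhs)
        x = sol[:n]
        z_old = z
        z = np.clip(x + u, lb, ub)
        u = u + x - z
        if it % check_every == 0 or it == max_iter:
            r_p = float(np.max(np.abs(x - z)))
            r_d = float(rho * np.max(np.abs(z - z_old)))
            scale = max(1.0, float(np.max(np.abs(x))))
            tol = eps_abs + eps_rel * scale
            if r_p < tol and r_d < tol:
                return QPResult(x, it, True, r_p, r_d)
            # residual balancing: refactor with a new rho when badly skewed
            if r_p > 100 * r_d and rho < 1e6:
                rho *= 10.0
                u /= 10.0
                lu = _factor(H_diag, S, rho)
            elif r_d > 100 * r_p and rho > 1e-6:
                rho /= 10.0
                u *= 10.0
                lu = _factor(H_diag, S, rho)
    return QPResult(x, it, False, r_p, r_d)
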