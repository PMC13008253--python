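"""Flux prediction from proteomics: quadratic program with embedded logit models.

Given per-reaction enzyme abundances E and k_app^max values, the predicted
flux distribution minimizes

    sum_{j in P} (v_j - E_j * kappmax_j * eta_hat_j(v))^2  +  w * sum_i v_i

subject to steady state (S v = 0), enzyme capacity (v_l <= E_l * kappmax_l
for every reaction l in Q with abundance and kappmax) and flux bounds, where
eta_hat_j = logistic(beta_j + sum_k alpha_jk * phi_k) is the learned
concentration-effect model evaluated at the flux-sums phi = S+ v of the very
flux vector being optimized.  P is the subset of Q whose regression models
passed the cross-validation quality threshold.

Because eta_hat is a logistic of linear functions of v inside a quadratic,
the problem is non-convex.  It is solved by damped fixed-point iteration:
evaluate eta_hat at the current flux-sums, freeze it, solve the resulting
convex QP, relax the flux-sums toward the new solution, and repeat until the
predicted eta stabilize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from ._qp import solve_box_qp
from .eta_regression import EtaModel, _logistic
from .flux_estimation import FluxDistribution, InfeasibleError, pfba
from .model_io import MetabolicModel, producer_matrix

__all__ = [
    "OptimizationSpec",
    "KineFluxResult",
    "apply_capacity_constraints",
    "build_spec",
    "solve_kineflux",
]

logger = logging.getLogger(__name__)

DEFAULT_W = 1e-2  # weight of the total-flux term in the objective
DEFAULT_R2_THRESHOLD = 0.6  # CV adjusted R^2 needed to enter the quadratic term


@dataclass
class OptimizationSpec:
    """Inputs of one per-condition flux prediction.

    ``eta_models`` defines the set P (reactions whose quality-filtered logit
    model enters the quadratic term); the index of ``abundance``/``kappmax``
    defines Q (reactions receiving a hard capacity cap).  P must be a subset
    of Q.
    """

    eta_models: dict[str, EtaModel]
    abundance: pd.Series  # E^C per reaction in Q (mmol gDW^-1)
    kappmax: pd.Series  # per reaction in Q (h^-1)
    w: float = DEFAULT_W
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("total-flux weight w must be positive")
        q = self.q_set
        missing = [r for r in self.eta_models if r not in q]
        if missing:
            raise ValueError(
                f"P must be a subset of Q; missing abundance/kappmax for: {sorted(missing)}"
            )

    @property
    def q_set(self) -> set[str]:
        return set(self.abundance.dropna().index) & set(self.kappmax.dropna().index)


@dataclass
class KineFluxResult:
    flux: FluxDistribution
    eta_pred: pd.Series  # predicted eta per reaction in P
    objective: float
    iterations: int
    converged: bool
    residual: float  # max relative change of eta over the final iteration
    objective_trajectory: list[float] = field(default_factory=list)
    forced_steps: int = 0  # steps accepted at the damping floor despite an objective increase


def build_spec(
    eta_models: dict[str, EtaModel],
    abundance: pd.Series,
    kappmax: pd.Series,
    w: float = DEFAULT_W,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> OptimizationSpec:
    """Filter models by CV quality (adjusted R^2 > threshold) and assemble a spec."""
    q = set(abundance.dropna().index) & set(kappmax.dropna().index)
    accepted = {
        rid: m
        for rid, m in eta_models.items()
        if m.cv_adj_r2 > r2_threshold and rid in q
    }
    return OptimizationSpec(
        eta_models=accepted,
        abundance=abundance,
        kappmax=kappmax,
        w=w,
        bounds=dict(bounds or {}),
    )


def apply_capacity_constraints(
    model: MetabolicModel, abundance: pd.Series, kappmax: pd.Series
) -> dict[str, tuple[float, float]]:
    """Per-reaction bound overrides enforcing v_l <= E_l * kappmax_l on Q.

    Reactions outside Q (no abundance or no kappmax) are untouched.  A cap
    falling below the model's lower bound is a data/model conflict and raises
    rather than silently clipping.
    """
    caps = (abundance * kappmax).dropna()
    if (caps < 0).any():
        bad = caps[caps < 0].index.tolist()
        raise ValueError(f"negative capacity (E * kappmax) for: {bad}")
    overrides: dict[str, tuple[float, float]] = {}
    rxn_set = set(model.reaction_ids)
    for rid, cap in caps.items():
        if rid not in rxn_set:
            continue
        j = model.reaction_index(rid)
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        new_ub = min(ub, float(cap))
        if new_ub < lb:
            raise InfeasibleError(
                f"capacity cap {new_ub:g} below lower bound {lb:g} for reaction {rid!r}"
            )
        overrides[rid] = (float(lb), new_ub)
    return overrides


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _solve_convex_qp(p_idx, targets, w, S, lb, ub, x0):
    """min sum_{j in P} (v_j - t_j)^2 + w * sum v  s.t.  S v = 0, lb <= v <= ub.

    Solved in units of the target scale (v = scale * x) so the subsolver sees
    O(1) quantities regardless of the absolute flux magnitude.
    """
    n = len(lb)
    scale = max(1.0, float(np.max(targets)) if len(targets) else 1.0)
    H_diag = np.zeros(n)
    H_diag[p_idx] = 2.0
    c = np.full(n, w / scale)
    c[p_idx] -= 2.0 * targets / scale
    res = solve_box_qp(
        H_diag, c, S, lb / scale, ub / scale,
        x0=np.clip(x0 / scale, lb / scale, ub / scale),
    )
    if not res.converged:
        logger.warning(
            "QP subproblem stopped at %d iterations (primal %.2e, dual %.2e)",
            res.iterations, res.primal_residual, res.dual_residual,
        )
    return np.clip(res.x * scale, lb, ub)


def _min_total_flux_lp(S, lb, ub, w):
    res = linprog(
        np.full(len(lb), w),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError("base constraint set (S v = 0 with bounds) is infeasible")
    if res.status != 0:
        raise RuntimeError(f"LP failed with status {res.status}: {res.message}")
    return res.x


def solve_kineflux(
    model: MetabolicModel,
    spec: OptimizationSpec,
    condition_id: str = "",
    init: FluxDistribution | None = None,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> KineFluxResult:
    """Predict a steady-state flux distribution compatible with learned eta models.

    Parameters
    ----------
    init
        Starting flux vector for the fixed-point iteration.  When omitted, a
        pFBA solution under the capacity constraints is used if the model has
        an objective reaction, else the minimal-total-flux vertex.  Fixed
        points of non-convex problems can depend on the start; the choice is
        recorded in the result's flux ``source``.
    damping
        Relaxation factor lambda on the flux-sum update,
        ``phi <- (1 - lambda) phi + lambda S+ v``.
    tol
        Convergence threshold on the max relative change of predicted eta.
    """
    if not model.irreversible and np.any(model.lower_bounds < 0):
        raise ValueError("model must be irreversible; call make_irreversible() first")
    overrides = dict(spec.bounds)
    for rid, bnd in apply_capacity_constraints(model, spec.abundance, spec.kappmax).items():
        if rid in overrides:
            lo = max(overrides[rid][0], bnd[0])
            hi = min(overrides[rid][1], bnd[1])
            if hi < lo:
                raise InfeasibleError(f"bounds and capacity cap conflict for {rid!r}")
            overrides[rid] = (lo, hi)
        else:
            overrides[rid] = bnd
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rid, (lo, hi) in overrides.items():
        j = model.reaction_index(rid)
        lb[j], ub[j] = lo, hi

    S = model.S.tocsr()
    Splus = producer_matrix(model).tocsr()
    rxn_ids = model.reaction_ids
    p_ids = [r for r in sorted(spec.eta_models) if r in set(rxn_ids)]

    if not p_ids:
        v = _min_total_flux_lp(S, lb, ub, spec.w)
        flux = FluxDistribution(condition_id, pd.Series(v, index=rxn_ids), float("nan"), "kineflux")
        obj = float(spec.w * v.sum())
        return KineFluxResult(flux, pd.Series(dtype=float), obj, 0, True, 0.0, [obj])

    p_idx = np.array([model.reaction_index(r) for r in p_ids])
    E = spec.abundance.loc[p_ids].to_numpy(dtype=float)
    kmax = spec.kappmax.loc[p_ids].to_numpy(dtype=float)
    models = [spec.eta_models[r] for r in p_ids]
    # coefficient matrix: eta_hat = logistic(beta + A phi)
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    A = np.zeros((len(p_ids), model.n_metabolites))
    beta = np.zeros(len(p_ids))
    for k, m in enumerate(models):
        beta[k] = m.beta
        for met, a in m.alpha.items():
            if met not in met_index:
                raise ValueError(
                    f"eta model for {m.reaction_id!r} references unknown metabolite {met!r}"
                )
            A[k, met_index[met]] = a

    # initialization
    if init is not None:
        v = init.values.reindex(rxn_ids).to_numpy(dtype=float)
        source = "kineflux"
    elif model.objective_reaction is not None:
        try:
            v = pfba(model, bounds=overrides, condition_id=condition_id).values.to_numpy()
        except InfeasibleError:
            raise
        source = "kineflux"
    else:
        v = _min_total_flux_lp(S, lb, ub, spec.w)
        source = "kineflux"

    def _objective(v_vec, eta_vec):
        d = v_vec[p_idx] - E * kmax * eta_vec
        return float(d @ d + spec.w * v_vec.sum())

    phi = Splus @ v
    eta_hat = _logistic(beta + A @ phi)
    trajectory: list[float] = []
    converged = False
    residual = np.inf
    lam = damping
    lam_min = 0.02
    forced_steps = 0
    it = 0
    for it in range(1, max_iter + 1):
        targets = E * kmax * eta_hat
        v_new = _solve_convex_qp(p_idx, targets, spec.w, S, lb, ub, v)
        phi_v = Splus @ v_new
        # accept the largest relaxation step that does not increase the
        # objective (steep eta models make the undamped map oscillate);
        # rejected trials only re-blend phi, the QP is not re-solved
        while True:
            phi_cand = (1.0 - lam) * phi + lam * phi_v
            eta_cand = _logistic(beta + A @ phi_cand)
            obj_cand = _objective(v_new, eta_cand)
            increased = trajectory and obj_cand > trajectory[-1] * (1.0 + 1e-8) + 1e-12
            if not increased:
                break
            if lam <= lam_min:
                forced_steps += 1
                break
            lam = max(0.5 * lam, lam_min)
        residual = float(
            np.max(np.abs(eta_cand - eta_hat) / np.maximum(np.abs(eta_hat), 1e-12))
        )
        v, phi, eta_hat = v_new, phi_cand, eta_cand
        trajectory.append(obj_cand)
        lam = min(1.05 * lam, damping)
        if residual < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "fixed-point iteration did not converge in %d iterations (residual %.3g)",
            max_iter, residual,
        )

    flux = FluxDistribution(condition_id, pd.Series(v, index=rxn_ids), float("nan"), source)
    eta_pred = pd.Series(eta_hat, index=p_ids, name="eta_pred")
    return KineFluxResult(
        flux=flux,
        eta_pred=eta_pred,
        objective=trajectory[-1],
        iterations=it,
        converged=converged,
        residual=residual,
        objective_trajectory=trajectory,
        forced_steps=forced_steps,
    )
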