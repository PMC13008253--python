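"""Flux balance analysis (FBA) and parsimonious FBA on irreversible networks.

Both solvers work on the irreversible form of a :class:`~kineflux.model_io.MetabolicModel`,
so every flux is non-negative and the parsimony objective is the plain sum of
fluxes.  Measured flux intervals (e.g. 13C-MFA confidence intervals) enter as
per-reaction bound overrides read from delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = [
    "FluxDistribution",
    "InfeasibleError",
    "UnboundedError",
    "fba",
    "pfba",
    "read_bounds_table",
    "write_flux_table",
]

#: relative tolerance at which the parsimony stage pins the optimal objective
OBJECTIVE_TOL = 1e-6
#: scale-aware steady-state tolerance: ||S v||_inf <= tol * max(1, ||v||_inf)
STEADY_STATE_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """The constraint set admits no flux distribution."""


class UnboundedError(RuntimeError):
    """The LP objective is unbounded above."""


@dataclass
class FluxDistribution:
    """A steady-state flux vector for one condition."""

    condition_id: str
    values: pd.Series  # flux per irreversible reaction
    objective_value: float
    source: str  # {"pfba", "fba", "kineflux", "external"}

    def __getitem__(self, rid: str) -> float:
        return float(self.values[rid])


def _resolve_bounds(
    model: MetabolicModel, bounds: dict[str, tuple[float, float]] | None
) -> tuple[np.ndarray, np.ndarray]:
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    if bounds:
        bad = [r for r in bounds if r not in set(model.reaction_ids)]
        if bad:
            raise KeyError(f"bound overrides reference unknown reactions: {sorted(bad)}")
        empty = [r for r, (lo, hi) in bounds.items() if lo > hi]
        if empty:
            raise InfeasibleError(
                f"empty bound interval (lb > ub) for reaction(s): {sorted(empty)}"
            )
        for rid, (lo, hi) in bounds.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = lo, hi
    return lb, ub


def _solve_lp(c, S, lb, ub, extra_A=None, extra_b=None, method="highs"):
    n = len(c)
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    if extra_A is not None:
        A_eq = sp.vstack([sp.csr_matrix(S), sp.csr_matrix(extra_A)])
        b_eq = np.concatenate([b_eq, np.atleast_1d(extra_b)])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method=method,
    )
    return res


def fba(
    model: MetabolicModel,
    bounds: dict[str, tuple[float, float]] | None = None,
    objective: str | None = None,
    condition_id: str = "",
    method: str = "highs",
) -> FluxDistribution:
    """Maximize the objective flux subject to ``Sv = 0`` and bounds.

    Returns one optimizer; with degenerate alternate optima the individual
    fluxes are solver-dependent, only the objective value is unique.
    """
    model = _require_irreversible(model)
    obj = objective or model.objective_reaction
    if obj is None:
        raise ValueError("no objective reaction set on the model and none supplied")
    lb, ub = _resolve_bounds(model, bounds)
    c = np.zeros(model.n_reactions)
    c[model.reaction_index(obj)] = -1.0  # linprog minimizes
    res = _solve_lp(c, model.S, lb, ub, method=method)
    _raise_on_status(res, bounds)
    v = pd.Series(res.x, index=model.reaction_ids, name=condition_id)
    return FluxDistribution(condition_id, v, float(-res.fun), "fba")


def pfba(
    model: MetabolicModel,
    bounds: dict[str, tuple[float, float]] | None = None,
    objective: str | None = None,
    condition_id: str = "",
    method: str = "highs",
) -> FluxDistribution:
    """Parsimonious FBA: maximize the objective, then minimize total flux.

    Stage 1 finds the optimal objective value z*; stage 2 minimizes the sum
    of (non-negative) fluxes subject to the objective flux being fixed at z*
    (as an equality, at relative tolerance :data:`OBJECTIVE_TOL`).
    """
    model = _require_irreversible(model)
    obj = objective or model.objective_reaction
    if obj is None:
        raise ValueError("no objective reaction set on the model and none supplied")
    lb, ub = _resolve_bounds(model, bounds)
    j_obj = model.reaction_index(obj)
    c1 = np.zeros(model.n_reactions)
    c1[j_obj] = -1.0
    res1 = _solve_lp(c1, model.S, lb, ub, method=method)
    _raise_on_status(res1, bounds)
    z_star = -res1.fun
    # stage 2: pin the objective, minimize total flux
    lb2, ub2 = lb.copy(), ub.copy()
    slack = OBJECTIVE_TOL * max(1.0, abs(z_star))
    lb2[j_obj] = max(lb2[j_obj], z_star - slack)
    ub2[j_obj] = min(ub2[j_obj], z_star + slack)
    c2 = np.ones(model.n_reactions)
    res2 = _solve_lp(c2, model.S, lb2, ub2, method=method)
    _raise_on_status(res2, bounds)
    v = pd.Series(res2.x, index=model.reaction_ids, name=condition_id)
    return FluxDistribution(condition_id, v, float(z_star), "pfba")


def _require_irreversible(model: MetabolicModel) -> MetabolicModel:
    if not model.irreversible and np.any(model.lower_bounds < 0):
        raise ValueError(
            "model has reversible reactions; call make_irreversible() first"
        )
    return model


def _raise_on_status(res, bounds) -> None:
    if res.status == 2:
        ids = sorted(bounds) if bounds else []
        raise InfeasibleError(
            "LP infeasible" + (f"; active bound overrides: {ids}" if ids else "")
        )
    if res.status == 3:
        raise UnboundedError("LP objective is unbounded; check exchange bounds")
    if res.status != 0:
        raise RuntimeError(f"LP solver failed with status {res.status}: {res.message}")


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

def read_bounds_table(path: str, sep: str = "\t") -> dict[str, tuple[float, float]]:
    """Read per-reaction bound overrides (columns: reaction_id, lb, ub)."""
    df = pd.read_csv(path, sep=sep)
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"bounds file {path!r} must have columns {sorted(required)}")
    return {
        str(row.reaction_id): (float(row.lb), float(row.ub))
        for row in df.itertuples(index=False)
    }


def write_flux_table(flux: FluxDistribution, path: str, sep: str = "\t") -> None:
    """Write a flux distribution as two columns: reaction_id, flux."""
    df = pd.DataFrame({"reaction_id": flux.values.index, "flux": flux.values.values})
    df.to_csv(path, sep=sep, index=False)
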