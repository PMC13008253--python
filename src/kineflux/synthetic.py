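"""Desk-scale synthetic networks with known kinetic ground truth.

The generator builds a small irreversible branched network — one uptake
feeding a hub metabolite, per-branch transport to a branch substrate, an
enzyme-catalyzed kinetic reaction per branch, transports draining the branch
products into a biomass-like sink (the first branch drains through a
pre-split reversible transport pair) — and samples matched
enzyme-abundance/flux data sets across conditions whose ground truth follows
the generative model

    v_j = kcat_j * E_j * eta_j,    eta_j = logistic(beta_j + sum_k alpha_jk * phi_k(v)),

i.e. the concentration effect of every kinetic reaction is an exact logistic
function of metabolite flux-sums (the well-specified case; an optional
Michaelis-Menten mode generates eta from saturation kinetics instead, to
probe misspecification).  Each kinetic reaction responds to its own
substrate's flux-sum with a negative coefficient (the in vivo saturation
drops as throughput rises), and a configurable fraction additionally respond
to another branch's substrate (a planted effector).  Because a substrate's
flux-sum equals the branch flux itself, each condition's flux vector solves
a scalar fixed-point equation per branch with a strictly decreasing
right-hand side — a unique root, found by bisection to machine precision —
and the uptake, transport and sink reactions absorb the stoichiometric slack
so that S v = 0 holds exactly.

The lowest-expression "reference" group is constructed as an exactly
self-consistent fixed point at essentially complete saturation
(``eta_ref``), for two reasons: it makes k_app^max an exact proxy for the
true kcat, and it makes the max-normalized concentration effects an exact
member of the logistic family, so that regression recovery on noiseless data
is sharp.  Lowering ``eta_ref`` probes the partially saturated (and hence
mildly misspecified) regime.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .eta_regression import build_training_table, select_models
from .kinetics import (
    ConditionDataset,
    build_kinetic_table,
    compute_flux_sum_table,
)
from .kineflux_opt import build_spec, solve_kineflux
from .model_io import MetabolicModel

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "FixtureBundle",
    "generate_network",
    "generate_conditions",
    "generate_bundle",
    "write_fixture",
    "end_to_end_recovery",
]

logger = logging.getLogger(__name__)

_LOGIT = lambda p: np.log(p / (1.0 - p))  # noqa: E731
_LOGISTIC = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731

BIG = 1e4  # default "unconstrained" flux bound


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults emulate a small strain panel: 25 reactions (7 kinetic branches),
    30 conditions in 15 replicate groups of two biological replicates, enzyme
    turnover numbers of 1-100 s^-1 (3.6e3-3.6e5 h^-1) and abundances such
    that fluxes are of order 1 mmol gDW^-1 h^-1.  Conditions differ by a
    global expression scale (log-uniform over ``scale_range``) and per-group
    reaction-level variation; replicates within a group differ only by small
    log-normal abundance jitter.
    """

    n_metabolites: int = 17
    n_reactions: int = 25
    n_conditions: int = 30
    n_replicate_groups: int = 15
    kcat_range: tuple[float, float] = (3.6e3, 3.6e5)  # h^-1
    km_range: tuple[float, float] = (0.5, 5.0)  # flux-sum scale (mm mode)
    noise_sd_logit: float = 0.0
    seed: int = 0
    topology: str = "branched"  # or "chain"
    # generative design of the concentration effects
    eta_ref: float = 1.0 - 1e-9  # saturation of the reference (lowest-expression) group
    eta_lo_range: tuple[float, float] = (0.4, 0.7)  # eta at the highest expression scale
    scale_range: tuple[float, float] = (1.3, 10.0)  # expression scale of other groups
    group_jitter_range: tuple[float, float] = (0.8, 1.25)  # per (reaction, group)
    replicate_jitter_sd: float = 0.02  # log-normal sd within a group
    frac_extra: float = 0.3  # fraction of kinetic reactions with one extra effector
    flux_scale: float = 1.0  # multiplies all branch fluxes (mmol gDW^-1 h^-1)
    mode: str = "logistic"  # or "mm" (Michaelis-Menten, misspecified for the regression)

    def __post_init__(self) -> None:
        if self.topology == "branched":
            if self.n_metabolites < 9 or self.n_metabolites % 2 == 0:
                raise ValueError(
                    "branched topology needs an odd n_metabolites >= 9 (2k + 3 for k branches)"
                )
            k = (self.n_metabolites - 3) // 2
            if self.n_reactions != 3 * k + 4:
                raise ValueError(
                    f"branched topology with {self.n_metabolites} metabolites has "
                    f"{3 * k + 4} reactions, not {self.n_reactions}"
                )
        elif self.topology == "chain":
            if self.n_metabolites < 2:
                raise ValueError("chain topology needs at least 2 metabolites")
            if self.n_reactions != self.n_metabolites + 1:
                raise ValueError(
                    f"chain topology with {self.n_metabolites} metabolites has "
                    f"{self.n_metabolites + 1} reactions"
                )
        else:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_conditions < 2 * self.n_replicate_groups:
            raise ValueError("need n_conditions >= 2 * n_replicate_groups (paired replicates)")
        if not 0 < self.eta_ref < 1:
            raise ValueError("eta_ref must lie strictly inside (0, 1)")
        for name in ("kcat_range", "km_range", "eta_lo_range", "scale_range", "group_jitter_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")

    @property
    def n_branches(self) -> int:
        return (self.n_metabolites - 3) // 2


@dataclass
class FixtureTruth:
    """Ground truth never exposed to the analysis pipeline."""

    kcat: pd.Series  # per kinetic reaction (h^-1)
    alpha: dict[str, dict[str, float]]  # reaction -> metabolite -> coefficient
    beta: pd.Series
    feature_sets: dict[str, tuple[str, ...]]  # reaction -> generating extra metabolites
    eta: pd.DataFrame  # true eta per (kinetic reaction, condition)
    eta_norm: pd.DataFrame  # eta / per-reaction max over conditions
    flux: pd.DataFrame  # true flux per (reaction, condition), steady state
    reference_condition: str


@dataclass
class FixtureBundle:
    model: MetabolicModel
    dataset: ConditionDataset  # observable data (fluxes may carry noise)
    truth: FixtureTruth
    spec: FixtureSpec
    kinetic_reactions: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def generate_network(spec: FixtureSpec) -> MetabolicModel:
    """Build the fixture network; deterministic given the spec.

    Branched topology with k branches: uptake -> hub M00; per branch j a
    transport T0j (M00 -> S0j), a kinetic reaction ENZ0j (S0j -> X0j) and a
    drain TRX0j (X0j -> BM); branch 1 passes through an extra intermediate
    Y01 via a pre-split reversible pair (TRX01_f / TRX01_b); biomass-like
    sink BM -> out.
    """
    if spec.topology == "chain":
        return _chain_network(spec)
    k = spec.n_branches
    mets = (
        ["M00"]
        + [f"S{i:02d}" for i in range(1, k + 1)]
        + [f"X{i:02d}" for i in range(1, k + 1)]
        + ["Y01", "BM"]
    )
    idx = {m: i for i, m in enumerate(mets)}
    cols: list[dict[str, float]] = []
    rxn_ids, subs, rules = [], [], []

    def add(rid, stoich, subsystem, rule=""):
        rxn_ids.append(rid)
        cols.append(stoich)
        subs.append(subsystem)
        rules.append(rule)

    add("UPT", {"M00": 1.0}, "Transport")
    for i in range(1, k + 1):
        add(f"T{i:02d}", {"M00": -1.0, f"S{i:02d}": 1.0}, "Transport")
    for i in range(1, k + 1):
        add(f"ENZ{i:02d}", {f"S{i:02d}": -1.0, f"X{i:02d}": 1.0},
            "Branch A" if i % 2 else "Branch B", f"g{i:04d}")
    add("TRX01_f", {"X01": -1.0, "Y01": 1.0}, "Transport")
    add("TRX01_b", {"Y01": -1.0, "X01": 1.0}, "Transport")
    add("TRY01", {"Y01": -1.0, "BM": 1.0}, "Transport")
    for i in range(2, k + 1):
        add(f"TRX{i:02d}", {f"X{i:02d}": -1.0, "BM": 1.0}, "Transport")
    add("SINK", {"BM": -1.0}, "Biomass")

    rows, cs, data = [], [], []
    for j, stoich in enumerate(cols):
        for m, c in stoich.items():
            rows.append(idx[m])
            cs.append(j)
            data.append(c)
    S = sp.coo_matrix((data, (rows, cs)), shape=(len(mets), len(rxn_ids))).tocsc()
    n = len(rxn_ids)
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=mets,
        S=S,
        lower_bounds=np.zeros(n),
        upper_bounds=np.full(n, BIG * spec.flux_scale),
        subsystems=subs,
        gene_rules=rules,
        objective_reaction="SINK",
        irreversible=True,
        split_map={r: (r.rsplit("_", 1)[0] if r.endswith(("_f", "_b")) else r,
                       -1 if r.endswith("_b") else 1) for r in rxn_ids},
    )


def _chain_network(spec: FixtureSpec) -> MetabolicModel:
    m = spec.n_metabolites
    mets = [f"M{i:02d}" for i in range(m)]
    rxn_ids = ["UPT"] + [f"R{i:02d}" for i in range(1, m)] + ["SINK"]
    rows, cs, data = [], [], []
    rows += [0]; cs += [0]; data += [1.0]
    for i in range(1, m):
        rows += [i - 1, i]; cs += [i, i]; data += [-1.0, 1.0]
    rows += [m - 1]; cs += [m]; data += [-1.0]
    S = sp.coo_matrix((data, (rows, cs)), shape=(m, m + 1)).tocsc()
    n = m + 1
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=mets,
        S=S,
        lower_bounds=np.zeros(n),
        upper_bounds=np.full(n, BIG * spec.flux_scale),
        subsystems=["Transport"] + ["Chain"] * (m - 1) + ["Biomass"],
        gene_rules=[""] + [f"g{i:04d}" for i in range(1, m)] + [""],
        objective_reaction="SINK",
        irreversible=True,
        split_map={r: (r, 1) for r in rxn_ids},
    )


# ---------------------------------------------------------------------------
# condition sampling
# ---------------------------------------------------------------------------

def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_conditions(model: MetabolicModel, spec: FixtureSpec) -> FixtureBundle:
    """Sample abundances and solve the per-condition flux fixed points.

    The first replicate of the first group is the exactly self-consistent
    reference condition at saturation ``eta_ref``; every other condition has
    strictly higher enzyme expression, which (with the negative flux-sum
    coefficients of the design) yields strictly lower eta, so the reference
    is the per-reaction saturation argmax.
    """
    if spec.topology != "branched":
        raise ValueError("condition generation requires the branched topology")
    rng = np.random.default_rng(spec.seed)
    k = spec.n_branches
    kin = [f"ENZ{i:02d}" for i in range(1, k + 1)]
    sub_mets = [f"S{i:02d}" for i in range(1, k + 1)]

    kcat = pd.Series(_loguniform(rng, *spec.kcat_range, size=k), index=kin, name="kcat")
    f_ref = pd.Series(rng.uniform(0.5, 1.5, size=k) * spec.flux_scale, index=kin)
    e_base = f_ref / (kcat * spec.eta_ref)  # reference (lowest) abundances

    # planted effectors: some branches respond to an earlier branch's substrate,
    # so the per-condition fixed points can be solved branch by branch
    n_extra = int(round(spec.frac_extra * k))
    extra_of: dict[str, str | None] = {r: None for r in kin}
    if spec.mode == "logistic" and n_extra > 0 and k > 1:
        which = rng.choice(np.arange(1, k), size=min(n_extra, k - 1), replace=False)
        for j in which:
            partner = int(rng.integers(0, j))
            extra_of[kin[j]] = sub_mets[partner]

    # coefficient design: eta falls from eta_ref at the reference flux to
    # roughly eta_lo at the highest expression scale
    eta_lo = rng.uniform(*spec.eta_lo_range, size=k)
    s_max = spec.scale_range[1]
    f_hi_est = s_max * f_ref.to_numpy() * eta_lo / spec.eta_ref
    alpha_sub = (_LOGIT(eta_lo) - _LOGIT(spec.eta_ref)) / (f_hi_est - f_ref.to_numpy())  # < 0
    alpha_extra: dict[str, dict[str, float]] = {}
    beta = {}
    # Michaelis constants, capped below the lowest-expression capacity so a
    # positive steady state exists on every branch in Michaelis-Menten mode
    km_raw = _loguniform(rng, *spec.km_range, size=k) * spec.flux_scale
    km = pd.Series(
        np.minimum(km_raw, 0.5 * f_ref.to_numpy() / spec.eta_ref), index=kin
    )
    for j, r in enumerate(kin):
        a = {sub_mets[j]: float(alpha_sub[j])}
        b = _LOGIT(spec.eta_ref) - alpha_sub[j] * float(f_ref.iloc[j])
        if extra_of[r] is not None:
            f_x_ref = float(f_ref.iloc[sub_mets.index(extra_of[r])])
            ax = -float(rng.uniform(0.4, 0.8)) / f_x_ref
            a[extra_of[r]] = ax
            b -= ax * f_x_ref
        alpha_extra[r] = a
        beta[r] = float(b)
    beta = pd.Series(beta)

    # condition layout: groups of replicates, group 0 is the saturated reference
    n_g = spec.n_replicate_groups
    sizes = np.full(n_g, spec.n_conditions // n_g)
    sizes[: spec.n_conditions % n_g] += 1
    s_group = np.concatenate([[1.0], _loguniform(rng, *spec.scale_range, size=n_g - 1)])
    u_group = np.vstack(
        [np.ones(k)] + [_loguniform(rng, *spec.group_jitter_range, size=k) for _ in range(n_g - 1)]
    )

    cond_ids, group_keys = [], {}
    E_cols, eta_cols, flux_cols = {}, {}, {}
    reference_condition = None
    for g in range(n_g):
        gid = f"G{g:02d}"
        for r_i in range(sizes[g]):
            cid = f"{gid}_r{r_i + 1}"
            cond_ids.append(cid)
            group_keys[cid] = gid
            if g == 0 and r_i == 0:
                jitter = np.ones(k)
                reference_condition = cid
            elif g == 0:
                # upward-only jitter keeps the first replicate the saturation argmax
                jitter = np.exp(np.abs(rng.normal(0.0, spec.replicate_jitter_sd, size=k)))
            else:
                jitter = np.exp(rng.normal(0.0, spec.replicate_jitter_sd, size=k))
            E = e_base.to_numpy() * s_group[g] * u_group[g] * jitter
            if g == 0 and r_i == 0:
                f = f_ref.to_numpy().copy()  # exact fixed point by construction
            else:
                f = _solve_branch_fixed_points(
                    E, kcat.to_numpy(), beta.to_numpy(), alpha_sub,
                    extra_of, alpha_extra, kin, sub_mets, spec, km.to_numpy(),
                )
            E_cols[cid] = E
            eta_cols[cid] = f / (E * kcat.to_numpy())
            flux_cols[cid] = f

    E_table = pd.DataFrame(E_cols, index=kin)
    eta_true = pd.DataFrame(eta_cols, index=kin)
    f_table = pd.DataFrame(flux_cols, index=kin)

    # observed fluxes: optional logit-scale noise on eta, re-balanced transports
    if spec.noise_sd_logit > 0:
        z = _LOGIT(np.clip(eta_true.to_numpy(), 1e-12, 1 - 1e-12))
        z_noisy = z + rng.normal(0.0, spec.noise_sd_logit, size=z.shape)
        f_obs = pd.DataFrame(
            _LOGISTIC(z_noisy) * E_table.to_numpy() * kcat.to_numpy()[:, None],
            index=kin, columns=eta_true.columns,
        )
    else:
        f_obs = f_table.copy()

    flux_true = _balance_transports(model, f_table, kin)
    flux_obs = _balance_transports(model, f_obs, kin)

    dataset = ConditionDataset(
        condition_ids=cond_ids,
        replicate_group=pd.Series(group_keys),
        enzyme_abundance=E_table,
        flux=flux_obs,
    )
    truth = FixtureTruth(
        kcat=kcat,
        alpha=alpha_extra,
        beta=beta,
        feature_sets={r: (extra_of[r],) if extra_of[r] else () for r in kin},
        eta=eta_true,
        eta_norm=eta_true.div(eta_true.max(axis=1), axis=0),
        flux=flux_true,
        reference_condition=reference_condition,
    )
    return FixtureBundle(model=model, dataset=dataset, truth=truth, spec=spec,
                         kinetic_reactions=kin)


def _solve_branch_fixed_points(
    E, kcat, beta, alpha_sub, extra_of, alpha_extra, kin, sub_mets, spec, km
):
    """Solve f_j = E_j kcat_j eta_j(f_j, f_extra) branch by branch.

    With a negative own-substrate coefficient the right-hand side is strictly
    decreasing in f_j, so the root is unique; effectors reference earlier
    branches only, making the system triangular.  In Michaelis-Menten mode
    the saturation term cap * x/(km + x) is concave with slope < 1 at the
    root, again unique and bracketed.
    """
    k = len(E)
    f = np.empty(k)
    for j in range(k):
        cap = E[j] * kcat[j]
        if spec.mode == "mm":
            # positive root of cap * x/(km + x) = x, i.e. x = cap - km
            if cap <= km[j]:
                raise RuntimeError(
                    f"branch {kin[j]}: capacity {cap:g} below Km {km[j]:g}; "
                    "no positive steady state in Michaelis-Menten mode"
                )
            def g(x, j=j, cap=cap):
                return cap * x / (km[j] + x) - x
            f[j] = brentq(g, km[j] * 1e-9, cap * (1 + 1e-9),
                          xtol=1e-15, rtol=8.9e-16, maxiter=200)
        else:
            extra_term = 0.0
            if extra_of[kin[j]] is not None:
                x_met = extra_of[kin[j]]
                extra_term = alpha_extra[kin[j]][x_met] * f[sub_mets.index(x_met)]
            a_own = alpha_sub[j]
            b = beta[j]

            def g(x, cap=cap, a_own=a_own, b=b, extra_term=extra_term):
                return cap * _LOGISTIC(b + a_own * x + extra_term) - x

            f[j] = brentq(g, 0.0, cap * (1 + 1e-9),
                          xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return f


def _balance_transports(model: MetabolicModel, f_kin: pd.DataFrame, kin) -> pd.DataFrame:
    """Extend kinetic fluxes to a full steady-state vector via the transports."""
    cols = {}
    k = len(kin)
    for cid in f_kin.columns:
        f = f_kin[cid].to_numpy(dtype=float)
        v = pd.Series(0.0, index=model.reaction_ids)
        total = float(np.sum(f))
        v["UPT"] = total
        for j in range(1, k + 1):
            v[f"T{j:02d}"] = f[j - 1]
            v[f"ENZ{j:02d}"] = f[j - 1]
        v["TRX01_f"] = f[0]
        v["TRX01_b"] = 0.0
        v["TRY01"] = f[0]
        for j in range(2, k + 1):
            v[f"TRX{j:02d}"] = f[j - 1]
        v["SINK"] = total
        cols[cid] = v
    return pd.DataFrame(cols)


def generate_bundle(spec: FixtureSpec | None = None, **overrides) -> FixtureBundle:
    """Convenience: network + conditions in one call."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    model = generate_network(spec)
    return generate_conditions(model, spec)


# ---------------------------------------------------------------------------
# file export (observable data and truth kept strictly apart)
# ---------------------------------------------------------------------------

def write_fixture(bundle: FixtureBundle, directory: str, sep: str = "\t") -> dict[str, str]:
    """Write model, abundance, flux and manifest files plus a separate truth file.

    The observable files (consumed by the pipeline) never contain ground-truth
    fields; everything the pipeline must not see lives in ``truth.json``.
    """
    from .model_io import save_model_json

    os.makedirs(directory, exist_ok=True)
    paths = {
        "model": os.path.join(directory, "model.json"),
        "abundance": os.path.join(directory, "abundance.tsv"),
        "flux": os.path.join(directory, "flux.tsv"),
        "manifest": os.path.join(directory, "manifest.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    save_model_json(bundle.model, paths["model"])
    bundle.dataset.enzyme_abundance.rename_axis("reaction_id").to_csv(paths["abundance"], sep=sep)
    bundle.dataset.flux.rename_axis("reaction_id").to_csv(paths["flux"], sep=sep)
    pd.DataFrame(
        {"condition_id": bundle.dataset.condition_ids,
         "replicate_group": [bundle.dataset.replicate_group[c] for c in bundle.dataset.condition_ids]}
    ).to_csv(paths["manifest"], sep=sep, index=False)
    truth = bundle.truth
    doc = {
        "kcat": truth.kcat.to_dict(),
        "alpha": truth.alpha,
        "beta": truth.beta.to_dict(),
        "feature_sets": {r: list(v) for r, v in truth.feature_sets.items()},
        "eta": truth.eta.to_dict(),
        "eta_norm": truth.eta_norm.to_dict(),
        "flux": truth.flux.to_dict(),
        "reference_condition": truth.reference_condition,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(doc, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# end-to-end harness
# ---------------------------------------------------------------------------

def end_to_end_recovery(
    bundle: FixtureBundle,
    test_fraction: float = 0.3,
    seed: int = 0,
    min_samples: int = 10,
    pool_size: int = 10,
    max_extra: int = 3,
    k_folds: int = 5,
    r2_threshold: float = 0.6,
    w: float = 1e-2,
    max_iter: int = 300,
    regression_only: bool = False,
) -> dict:
    """Run the full pipeline on observable data only and score it against truth.

    Replicate groups are split into training and held-out sets; apparent
    catalytic rates, eta and flux-sums are computed on the training
    conditions, logit models selected by grouped CV, and (unless
    ``regression_only``) held-out flux distributions predicted from abundances
    alone and compared to the true fluxes per reaction.
    """
    ds = bundle.dataset
    rng = np.random.default_rng(seed)
    groups = sorted(ds.replicate_group.unique())
    n_test = max(1, int(round(test_fraction * len(groups))))
    test_groups = set(np.array(groups)[rng.permutation(len(groups))[:n_test]])
    train_conds = [c for c in ds.condition_ids if ds.replicate_group[c] not in test_groups]
    test_conds = [c for c in ds.condition_ids if ds.replicate_group[c] in test_groups]

    # apparent catalytic rates and their maxima use every condition (the
    # saturating condition must inform k_app^max); regression training below
    # is restricted to the training conditions only
    kin_table = build_kinetic_table(ds)
    fluxsums = compute_flux_sum_table(bundle.model, ds.flux[train_conds])
    tables = build_training_table(
        kin_table.eta[train_conds], fluxsums, bundle.model, ds.replicate_group,
        min_samples=min_samples,
    )
    models = select_models(
        tables, max_extra=max_extra, k_folds=k_folds, seed=seed, pool_size=pool_size
    )

    truth = bundle.truth
    kin = [r for r in bundle.kinetic_reactions if r in kin_table.kapp_max.index]
    kcat_err = (
        (kin_table.kapp_max.loc[kin] - truth.kcat.loc[kin]).abs() / truth.kcat.loc[kin]
    )
    matches = [
        set(models[r].extra_metabolites) == set(truth.feature_sets[r])
        for r in models if r in truth.feature_sets
    ]
    report = {
        "n_train_conditions": len(train_conds),
        "n_test_conditions": len(test_conds),
        "n_models": len(models),
        "kappmax_rel_err_max": float(kcat_err.max()) if len(kin) else float("nan"),
        "cv_adj_r2_mean": float(np.mean([m.cv_adj_r2 for m in models.values()]))
        if models else float("nan"),
        "feature_set_match_frac": float(np.mean(matches)) if matches else float("nan"),
        "models": models,
    }
    if regression_only:
        return report

    accepted = {r: m for r, m in models.items() if m.cv_adj_r2 > r2_threshold}
    report["n_P"] = len(accepted)
    pred_cols = {}
    for cid in test_conds:
        spec_c = build_spec(
            accepted,
            abundance=ds.enzyme_abundance[cid],
            kappmax=kin_table.kapp_max,
            w=w,
            r2_threshold=r2_threshold,
        )
        result = solve_kineflux(bundle.model, spec_c, condition_id=cid, max_iter=max_iter)
        pred_cols[cid] = result.flux.values
    if pred_cols and accepted:
        pred = pd.DataFrame(pred_cols)
        true_flux = truth.flux[test_conds]
        rs = []
        for rid in bundle.kinetic_reactions:
            t = true_flux.loc[rid].to_numpy(dtype=float)
            p = pred.loc[rid, test_conds].to_numpy(dtype=float)
            if np.std(t) > 0 and np.std(p) > 0:
                rs.append(float(np.corrcoef(p, t)[0, 1]))
        report["heldout_pearson_median"] = float(np.median(rs)) if rs else float("nan")
        report["heldout_pearson"] = rs
        report["predicted_flux"] = pred
    else:
        report["heldout_pearson_median"] = float("nan")
        report["heldout_pearson"] = []
    return report
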