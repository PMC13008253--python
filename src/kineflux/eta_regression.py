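"""Logit regression of metabolite concentration effects on flux-sums.

For each reaction the response is eta across conditions and the predictors
are metabolite flux-sums: the reaction's substrates always enter, plus up to
three additional metabolites chosen by exhaustive subset search.  The model

    eta = 1 / (1 + exp(-(beta + sum_k alpha_k phi_k)))

keeps predictions inside (0, 1).  Fitting is a logit transform of the clipped
response followed by ordinary least squares — closed-form and deterministic.
Candidate subsets are scored by grouped five-fold cross-validation with the
adjusted coefficient of determination, never splitting biological replicates
of one strain across folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LogitLinearRegression",
    "EtaModel",
    "TrainingTable",
    "FitError",
    "fit_logit",
    "enumerate_feature_sets",
    "grouped_cv_adjusted_r2",
    "group_folds",
    "build_training_table",
    "screen_candidate_pool",
    "select_model",
    "select_models",
    "extract_regulator_candidates",
    "save_eta_models",
    "load_eta_models",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6


class FitError(RuntimeError):
    """The regression could not be fit (e.g. rank-deficient predictors)."""


def _logistic(z: np.ndarray) -> np.ndarray:
    # clamped so the result stays strictly inside (0, 1) in float64:
    # sigma(36.7) is the largest representable value below 1
    z = np.clip(z, -700.0, 36.7)
    return 1.0 / (1.0 + np.exp(-z))


class LogitLinearRegression(RegressorMixin, BaseEstimator):
    """Bounded-response regression via logit transform + ordinary least squares.

    The response is clipped to ``[epsilon, 1 - epsilon]``, transformed with
    ``log(y / (1 - y))`` and regressed on the predictors with an intercept by
    OLS.  Predictions apply the inverse (logistic) transform, so they lie
    strictly in (0, 1) for any finite input.

    Because eta is normalized by its per-reaction maximum, every reaction has
    one condition with a response of exactly 1; after clipping, that row
    becomes a large-leverage outlier on the logit scale.  With
    ``refine=True`` the transform+OLS estimate is therefore used only to
    initialize a Gauss-Newton nonlinear least-squares fit on the eta scale,
    which treats saturated responses gracefully (model selection uses this
    mode; the plain transform+OLS estimator remains available).

    Parameters
    ----------
    epsilon : float, default 1e-6
        Clipping bound protecting the logit transform at responses of 0 or 1.
    refine : bool, default False
        Refine the coefficients by nonlinear least squares on the eta scale.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Per-predictor coefficients (alpha).
    intercept_ : float
        Intercept (beta).
    """

    def __init__(self, epsilon: float = DEFAULT_EPSILON, refine: bool = False):
        self.epsilon = epsilon
        self.refine = refine

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if len(y) != n:
            raise ValueError(f"X has {n} rows but y has {len(y)}")
        if np.any((y <= 0) | (y > 1)):
            raise ValueError("responses must lie in (0, 1]")
        if n < p + 2:
            raise FitError(f"need at least {p + 2} rows for {p} predictors, got {n}")
        yc = np.clip(y, self.epsilon, 1.0 - self.epsilon)
        z = np.log(yc / (1.0 - yc))
        A = np.column_stack([np.ones(n), X])
        # rank check with column pivoting so the offending columns can be named
        _, R, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int(np.sum(diag > tol))
        if rank < p + 1:
            bad = sorted(piv[rank:])
            names = [("intercept" if j == 0 else f"column {j - 1}") for j in bad]
            raise FitError(f"rank-deficient predictor matrix; collinear: {names}")
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.n_features_in_ = p
        if self.refine:
            theta = self._refine_eta_scale(A, y, coef)
            self.intercept_ = float(theta[0])
            self.coef_ = theta[1:]
        return self

    @staticmethod
    def _refine_eta_scale(A: np.ndarray, y: np.ndarray, theta0: np.ndarray) -> np.ndarray:
        from scipy.optimize import least_squares

        def resid(theta):
            return _logistic(A @ theta) - y

        def jac(theta):
            p = _logistic(A @ theta)
            return A * (p * (1.0 - p))[:, None]

        sol = least_squares(
            resid, theta0, jac=jac, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        return sol.x

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return _logistic(self.intercept_ + X @ self.coef_)


def fit_logit(
    phi_rows, eta, epsilon: float = DEFAULT_EPSILON
) -> tuple[np.ndarray, float]:
    """Fit the logit model; returns ``(alpha, beta)``."""
    est = LogitLinearRegression(epsilon=epsilon).fit(phi_rows, eta)
    return est.coef_, est.intercept_


# ---------------------------------------------------------------------------
# feature-subset enumeration
# ---------------------------------------------------------------------------

def enumerate_feature_sets(
    substrates, candidate_pool, max_extra: int = 3
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All candidate feature sets: the substrates plus 0..max_extra pool metabolites.

    Returns ``(substrates, extras)`` pairs in deterministic order: by subset
    size, then lexicographically by metabolite id.  The count is
    ``sum_{k=0}^{max_extra} C(|pool|, k)`` — e.g. two substrates with a
    four-metabolite pool yield 1 + 4 + 6 + 4 = 15 candidate models.
    """
    substrates = tuple(sorted(substrates))
    pool = sorted(candidate_pool)
    overlap = set(substrates) & set(pool)
    if overlap:
        raise ValueError(f"candidate pool overlaps substrates: {sorted(overlap)}")
    if max_extra < 0:
        raise ValueError("max_extra must be >= 0")
    out = []
    for k in range(min(max_extra, len(pool)) + 1):
        for extras in combinations(pool, k):
            out.append((substrates, extras))
    return out


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

def group_folds(groups, k_folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Partition row indices into folds that never split a replicate group.

    Unique group labels are shuffled deterministically by ``seed`` and dealt
    into ``k_folds`` near-equal parts; a fold's row set is the union of its
    groups' rows.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < k_folds:
        raise ValueError(
            f"only {len(uniq)} replicate groups for {k_folds} folds; lower k_folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    parts = np.array_split(uniq[order], k_folds)
    return [np.flatnonzero(np.isin(groups, part)) for part in parts]


def grouped_cv_adjusted_r2(
    phi_rows,
    eta,
    groups,
    k_folds: int = 5,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    refine: bool = False,
) -> float:
    """Mean adjusted R^2 of the logit model over grouped CV folds.

    Per fold the model is fit on the training groups and evaluated on the
    held-out rows *on the eta scale*: R^2 = 1 - SS_res/SS_tot, then
    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) with n held-out rows and p
    predictors.  Folds too small for the adjustment (n - p - 1 <= 0)
    contribute the unadjusted R^2.  A fold whose held-out response is
    (numerically) constant — standard deviation below 1e-6 — has no defined
    R^2 (the total sum of squares is pure rounding noise) and is skipped.
    """
    X = np.asarray(phi_rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(eta, dtype=float)
    p = X.shape[1]
    scores = []
    for test_idx in group_folds(groups, k_folds=k_folds, seed=seed):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        est = LogitLinearRegression(epsilon=epsilon, refine=refine).fit(
            X[train_mask], y[train_mask]
        )
        pred = est.predict(X[test_idx])
        resid = y[test_idx] - pred
        if float(np.std(y[test_idx])) <= 1e-6:
            logger.debug("numerically constant held-out response; fold skipped")
            continue
        ss_tot = float(np.sum((y[test_idx] - y[test_idx].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        n = len(test_idx)
        if n - p - 1 > 0:
            r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        else:
            logger.debug("fold of size %d too small to adjust for p=%d; using raw R^2", n, p)
        scores.append(r2)
    if not scores:
        raise FitError("no fold produced a defined R^2")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# training tables and model selection
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Per-reaction regression data: flux-sum predictors and eta response."""

    reaction_id: str
    phi: pd.DataFrame  # conditions x metabolites (all metabolites, columns = ids)
    eta: pd.Series  # response per condition, values in (0, 1]
    groups: pd.Series  # replicate group per condition
    substrates: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.eta)


@dataclass
class EtaModel:
    """A selected logit model for one reaction's concentration effect."""

    reaction_id: str
    substrate_metabolites: tuple[str, ...]
    extra_metabolites: tuple[str, ...]
    alpha: dict[str, float]  # metabolite id -> coefficient
    beta: float
    cv_adj_r2: float
    n_train: int

    @property
    def features(self) -> tuple[str, ...]:
        return self.substrate_metabolites + self.extra_metabolites

    def predict(self, phi) -> np.ndarray | float:
        """Predicted eta from flux-sums (Series/DataFrame indexed by metabolite)."""
        a = np.array([self.alpha[m] for m in self.features])
        if isinstance(phi, pd.DataFrame):
            X = phi.loc[list(self.features)].to_numpy(dtype=float).T
            return _logistic(self.beta + X @ a)
        vals = np.array([float(phi[m]) for m in self.features])
        return float(_logistic(self.beta + vals @ a))


def build_training_table(
    eta: pd.DataFrame,
    fluxsums: pd.DataFrame,
    model,
    groups: pd.Series,
    min_samples: int = 10,
) -> dict[str, TrainingTable]:
    """Assemble one regression table per reaction with enough observations.

    Keeps reactions whose eta is defined in at least ``min_samples``
    conditions; substrates are read off the negative stoichiometric
    coefficients.  Pure-source reactions (no substrates) are excluded.
    """
    tables: dict[str, TrainingTable] = {}
    for rid in eta.index:
        row = eta.loc[rid].dropna()
        if len(row) < min_samples:
            continue
        substrates = tuple(sorted(model.substrates_of(rid)))
        if not substrates:
            logger.info("reaction %s has no substrates; excluded from regression", rid)
            continue
        conds = [c for c in row.index if c in fluxsums.columns]
        if len(conds) < min_samples:
            continue
        tables[rid] = TrainingTable(
            reaction_id=rid,
            phi=fluxsums[conds].T,  # conditions x metabolites
            eta=row.loc[conds],
            groups=groups.loc[conds],
            substrates=substrates,
        )
    return tables


def screen_candidate_pool(
    table: TrainingTable,
    pool_size: int = 15,
    epsilon: float = DEFAULT_EPSILON,
    refine: bool = True,
) -> list[str]:
    """Pre-screen extra-metabolite candidates for the subset search.

    Exhaustive triplets over every network metabolite are combinatorially
    infeasible at genome scale, so candidates are ranked by the absolute
    Pearson correlation of their flux-sum profile with the eta-scale
    residuals of the substrates-only fit, keeping the top ``pool_size``.
    Metabolites with constant profiles are not rankable and are dropped.
    """
    X_sub = table.phi[list(table.substrates)].to_numpy(dtype=float)
    est = LogitLinearRegression(epsilon=epsilon, refine=refine).fit(X_sub, table.eta.to_numpy())
    resid = table.eta.to_numpy() - est.predict(X_sub)
    scores: list[tuple[float, str]] = []
    resid_sd = resid.std()
    for met in table.phi.columns:
        if met in table.substrates:
            continue
        prof = table.phi[met].to_numpy(dtype=float)
        if prof.std() == 0 or resid_sd == 0:
            continue
        r = float(np.corrcoef(prof, resid)[0, 1])
        if np.isfinite(r):
            scores.append((-abs(r), met))
    scores.sort()
    return [met for _, met in scores[:pool_size]]


def select_model(
    table: TrainingTable,
    candidate_pool=None,
    max_extra: int = 3,
    k_folds: int = 5,
    seed: int = 0,
    pool_size: int = 15,
    epsilon: float = DEFAULT_EPSILON,
    refine: bool = True,
    score_tol: float = 1e-4,
) -> EtaModel | None:
    """Exhaustive feature-subset search maximizing grouped-CV adjusted R^2.

    Every candidate feature set (substrates plus up to ``max_extra`` pool
    metabolites) is scored by :func:`grouped_cv_adjusted_r2`; the winner is
    refit on all rows.  Scores within ``score_tol`` of each other count as
    tied; ties break toward fewer extra metabolites, then lexicographic
    order, making selection deterministic for a given seed.  Returns ``None``
    when no candidate can be fit at all.
    """
    if candidate_pool is None:
        candidate_pool = screen_candidate_pool(
            table, pool_size=pool_size, epsilon=epsilon, refine=refine
        )
    candidate_pool = [m for m in candidate_pool if m not in table.substrates]
    best: tuple | None = None
    for substrates, extras in enumerate_feature_sets(table.substrates, candidate_pool, max_extra):
        feats = list(substrates) + list(extras)
        X = table.phi[feats].to_numpy(dtype=float)
        try:
            score = grouped_cv_adjusted_r2(
                X, table.eta.to_numpy(), table.groups.to_numpy(),
                k_folds=k_folds, seed=seed, epsilon=epsilon, refine=refine,
            )
        except FitError as exc:
            logger.debug("feature set %s unfit for %s: %s", feats, table.reaction_id, exc)
            continue
        if (
            best is None
            or score > best[3] + score_tol
            or (score > best[3] - score_tol and (len(extras), extras) < best[0])
        ):
            best = ((len(extras), extras), substrates, extras, score)
    if best is None:
        logger.info("reaction %s: every candidate fit failed; excluded", table.reaction_id)
        return None
    _, substrates, extras, score = best
    feats = list(substrates) + list(extras)
    try:
        est = LogitLinearRegression(epsilon=epsilon, refine=refine).fit(
            table.phi[feats].to_numpy(dtype=float), table.eta.to_numpy()
        )
        alpha, beta = est.coef_, est.intercept_
    except FitError:
        logger.info("reaction %s: winning set failed final refit; excluded", table.reaction_id)
        return None
    return EtaModel(
        reaction_id=table.reaction_id,
        substrate_metabolites=substrates,
        extra_metabolites=extras,
        alpha={m: float(a) for m, a in zip(feats, alpha)},
        beta=float(beta),
        cv_adj_r2=float(score),
        n_train=table.n_samples,
    )


def select_models(tables: dict[str, TrainingTable], **kwargs) -> dict[str, EtaModel]:
    """Run :func:`select_model` per reaction, dropping unfittable ones."""
    out: dict[str, EtaModel] = {}
    for rid, table in tables.items():
        m = select_model(table, **kwargs)
        if m is not None:
            out[rid] = m
    return out


# ---------------------------------------------------------------------------
# regulator candidates
# ---------------------------------------------------------------------------

def extract_regulator_candidates(
    model: EtaModel, fluxsums: pd.DataFrame, corr_threshold: float = 0.8
) -> set[str]:
    """Candidate effectors: the selected extras plus feature-correlated alternates.

    Any metabolite whose flux-sum profile across conditions has Pearson
    correlation above ``corr_threshold`` with a selected extra metabolite's
    profile is statistically interchangeable with it and is reported too.
    Constant profiles have undefined correlation and are skipped.
    """
    out = set(model.extra_metabolites)
    for extra in model.extra_metabolites:
        ref = fluxsums.loc[extra].to_numpy(dtype=float)
        if ref.std() == 0:
            logger.info("extra metabolite %s has a constant flux-sum profile; skipped", extra)
            continue
        for met in fluxsums.index:
            if met == extra or met in out:
                continue
            prof = fluxsums.loc[met].to_numpy(dtype=float)
            if prof.std() == 0:
                continue
            r = float(np.corrcoef(ref, prof)[0, 1])
            if r > corr_threshold:
                out.add(met)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_eta_models(models: dict[str, EtaModel], path: str) -> None:
    """One JSON record per reaction: features, coefficients, intercept, CV score."""
    doc = {
        rid: {
            "substrate_metabolites": list(m.substrate_metabolites),
            "extra_metabolites": list(m.extra_metabolites),
            "alpha": m.alpha,
            "beta": m.beta,
            "cv_adj_r2": m.cv_adj_r2,
            "n_train": m.n_train,
        }
        for rid, m in models.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_eta_models(path: str) -> dict[str, EtaModel]:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        rid: EtaModel(
            reaction_id=rid,
            substrate_metabolites=tuple(rec["substrate_metabolites"]),
            extra_metabolites=tuple(rec["extra_metabolites"]),
            alpha={k: float(v) for k, v in rec["alpha"].items()},
            beta=float(rec["beta"]),
            cv_adj_r2=float(rec["cv_adj_r2"]),
            n_train=int(rec["n_train"]),
        )
        for rid, rec in doc.items()
    }
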