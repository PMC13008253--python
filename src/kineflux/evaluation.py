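"""Scoring predicted flux distributions against estimated fluxes.

Implements the evaluation statistics used to judge flux predictions:
per-reaction Pearson correlation and MSE across conditions (restricted to
reactions with mostly nonzero estimated flux), per-condition correlation of
log-transformed fluxes, classification of reactions as "well-predicted" by a
pointwise prediction-interval band around the log-log regression line,
hypergeometric subsystem enrichment of well-predicted reactions, method
comparison with paired t-tests, and precision/recall of predicted regulator
candidates against known effector sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "per_reaction_correlation",
    "log_transform_fluxes",
    "well_predicted_band",
    "per_condition_metrics",
    "subsystem_enrichment",
    "compare_methods",
    "regulator_overlap",
]

logger = logging.getLogger(__name__)

LOG_CONSTANT = 1e-4  # added before taking logs, so zero fluxes stay finite


@dataclass
class EvaluationReport:
    per_reaction: pd.DataFrame
    per_condition: pd.DataFrame
    enrichment: pd.DataFrame

    def write(self, directory: str, sep: str = "\t") -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.per_reaction.to_csv(os.path.join(directory, "per_reaction.tsv"), sep=sep, index=False)
        self.per_condition.to_csv(os.path.join(directory, "per_condition.tsv"), sep=sep, index=False)
        self.enrichment.to_csv(os.path.join(directory, "enrichment.tsv"), sep=sep, index=False)


def per_reaction_correlation(
    pred: pd.DataFrame, est: pd.DataFrame, min_nonzero_frac: float = 0.8
) -> pd.DataFrame:
    """Pearson r and MSE per reaction across conditions.

    Only reactions whose *estimated* flux is nonzero in at least
    ``min_nonzero_frac`` of the conditions are evaluated.  A constant vector
    has undefined correlation; such reactions keep their MSE and get NaN r.
    """
    conds = [c for c in pred.columns if c in est.columns]
    rows = []
    for rid in est.index:
        if rid not in pred.index:
            continue
        e = est.loc[rid, conds].to_numpy(dtype=float)
        p = pred.loc[rid, conds].to_numpy(dtype=float)
        ok = ~(np.isnan(e) | np.isnan(p))
        e, p = e[ok], p[ok]
        if len(e) == 0:
            continue
        if np.count_nonzero(e) / len(e) < min_nonzero_frac:
            continue
        mse = float(np.mean((p - e) ** 2))
        if np.std(e) == 0 or np.std(p) == 0:
            r, pval = np.nan, np.nan
        else:
            r, pval = stats.pearsonr(p, e)
        rows.append((rid, float(r), float(pval) if pval == pval else np.nan, mse, len(e)))
    return pd.DataFrame(
        rows, columns=["reaction_id", "pearson_r", "p_value", "mse", "n_conditions"]
    )


def log_transform_fluxes(flux, constant: float = LOG_CONSTANT):
    """Natural log of (flux + constant); the constant keeps zeros finite."""
    arr = np.asarray(flux, dtype=float) if not isinstance(flux, (pd.Series, pd.DataFrame)) else flux
    if (np.asarray(arr) < 0).any():
        raise ValueError("fluxes must be non-negative before log transformation")
    return np.log(arr + constant)


def well_predicted_band(
    pred_log: np.ndarray, est_log: np.ndarray, confidence: float = 0.90
) -> tuple[np.ndarray, float]:
    """Flag points inside the pointwise prediction interval of the log-log fit.

    An OLS line of estimated on predicted log fluxes is fit; each point is
    classified by the standard prediction interval at the given confidence
    (t quantile with n-2 degrees of freedom, leverage-adjusted).  Returns the
    per-point flags and the fraction inside.  Reactions inside the band are
    considered to have well-predicted fluxes.
    """
    x = np.asarray(pred_log, dtype=float)
    y = np.asarray(est_log, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points to fit a prediction band")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("all predicted values identical; band undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted
    dof = n - 2
    s = np.sqrt(float(np.sum(resid**2)) / dof)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    half_width = tq * s * np.sqrt(1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx)
    inside = np.abs(resid) <= half_width
    return inside, float(np.mean(inside))


def per_condition_metrics(
    pred: pd.DataFrame,
    est: pd.DataFrame,
    constant: float = LOG_CONSTANT,
    confidence: float = 0.90,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Log-scale Pearson, MSE and well-predicted fraction per condition.

    Returns the per-condition table and, for each condition, the boolean
    well-predicted flag per reaction (for downstream enrichment analysis).
    """
    conds = [c for c in pred.columns if c in est.columns]
    common = est.index.intersection(pred.index)
    rows, flags = [], {}
    for c in conds:
        e = log_transform_fluxes(est.loc[common, c].to_numpy(dtype=float), constant)
        p = log_transform_fluxes(pred.loc[common, c].to_numpy(dtype=float), constant)
        r = float(stats.pearsonr(p, e)[0]) if np.std(e) > 0 and np.std(p) > 0 else np.nan
        mse = float(np.mean((p - e) ** 2))
        inside, frac = well_predicted_band(p, e, confidence)
        flags[c] = pd.Series(inside, index=common)
        rows.append((c, r, mse, frac))
    table = pd.DataFrame(
        rows, columns=["condition_id", "pearson_r_log", "mse_log", "fraction_well_predicted"]
    )
    return table, flags


def subsystem_enrichment(
    flags: pd.Series, subsystems: pd.Series, alpha: float = 0.02
) -> pd.DataFrame:
    """Hypergeometric enrichment of well-predicted reactions per subsystem.

    Upper-tail test: with N evaluated reactions of which n are well-predicted,
    a subsystem of size K containing k well-predicted ones gets
    p = P(X >= k), X ~ Hypergeom(N, n, K).  Bonferroni correction multiplies
    by the number of tested subsystems; a subsystem is significant when the
    corrected p-value is below ``alpha``.
    """
    common = flags.index.intersection(subsystems.index)
    missing = flags.index.difference(subsystems.index)
    if len(missing):
        raise ValueError(f"flagged reactions without subsystem label: {list(missing)}")
    flags = flags.loc[common].astype(bool)
    subsystems = subsystems.loc[common]
    N = len(flags)
    n_well = int(flags.sum())
    rows = []
    tested = [s for s, grp in flags.groupby(subsystems) if len(grp) > 0]
    m = len(tested)
    for s, grp in flags.groupby(subsystems):
        K = len(grp)
        if K == 0:
            continue
        k = int(grp.sum())
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, n_well, K))
        p_bonf = min(1.0, p * m)
        rows.append((s, k, K, n_well, N, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(
        rows,
        columns=[
            "subsystem", "k_well", "K_subsystem", "n_well_total", "N_total",
            "hypergeom_p", "bonferroni_p", "significant",
        ],
    )


def compare_methods(
    pred_sets: dict[str, pd.DataFrame],
    est: pd.DataFrame,
    constant: float = LOG_CONSTANT,
    min_nonzero_frac: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary metrics per method plus paired t-tests between methods.

    Per method: mean +/- SD of per-condition log-flux Pearson and MSE, and
    per-reaction mean r / MSE under the nonzero-fraction rule.  Paired
    two-sided t-tests compare each pair of methods on the per-condition
    Pearson vector; identical vectors are a degenerate case reported as p=1.
    """
    summaries, percond = [], {}
    for name, pred in pred_sets.items():
        cond_table, _ = per_condition_metrics(pred, est, constant)
        rxn_table = per_reaction_correlation(pred, est, min_nonzero_frac)
        percond[name] = cond_table.set_index("condition_id")["pearson_r_log"]
        summaries.append(
            (
                name,
                float(cond_table.pearson_r_log.mean()), float(cond_table.pearson_r_log.std(ddof=1)),
                float(cond_table.mse_log.mean()), float(cond_table.mse_log.std(ddof=1)),
                float(rxn_table.pearson_r.mean()), float(rxn_table.mse.mean()),
            )
        )
    summary = pd.DataFrame(
        summaries,
        columns=[
            "method", "cond_pearson_mean", "cond_pearson_sd", "cond_mse_mean",
            "cond_mse_sd", "rxn_pearson_mean", "rxn_mse_mean",
        ],
    )
    tests = []
    names = list(pred_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = percond[a].align(percond[b], join="inner")
            if len(va) < 2:
                logger.info("fewer than 2 shared conditions for %s vs %s; t-test skipped", a, b)
                continue
            diff = va.to_numpy() - vb.to_numpy()
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0  # degenerate: identical methods
            else:
                t, p = stats.ttest_rel(va, vb)
            tests.append((a, b, float(t), float(p), len(va)))
    ttests = pd.DataFrame(tests, columns=["method_a", "method_b", "t_stat", "p_value", "n"])
    return summary, ttests


def regulator_overlap(
    predicted_sets: dict[str, set[str]], known_sets: dict[str, set[str]]
) -> dict:
    """Precision/recall of predicted regulators against known effector sets.

    Overall values pool (reaction, metabolite) pairs over all reactions;
    per-reaction values are also reported (undefined when a reaction has no
    predictions), since pooling and averaging can differ.
    """
    tp = pred_total = known_total = 0
    per_rxn = []
    for rid in sorted(set(predicted_sets) | set(known_sets)):
        pred = predicted_sets.get(rid, set())
        known = known_sets.get(rid, set())
        hits = len(pred & known)
        tp += hits
        pred_total += len(pred)
        known_total += len(known)
        per_rxn.append(
            (
                rid,
                hits / len(pred) if pred else np.nan,
                hits / len(known) if known else np.nan,
            )
        )
    table = pd.DataFrame(per_rxn, columns=["reaction_id", "precision", "recall"])
    return {
        "precision_overall": tp / pred_total if pred_total else np.nan,
        "recall_overall": tp / known_total if known_total else np.nan,
        "precision_mean": float(table.precision.mean()),
        "recall_mean": float(table.recall.mean()),
        "precision_median": float(table.precision.median()),
        "recall_median": float(table.recall.median()),
        "per_reaction": table,
    }
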