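"""Apparent catalytic rates, metabolite concentration effects and flux-sums.

The flux v through an enzyme-catalyzed reaction decomposes as

    v = kcat * E * eta,

where kcat is the turnover number, E the enzyme abundance and eta in (0, 1]
the metabolite concentration effect — the fraction of the maximal catalytic
capacity realized in vivo (substrate saturation, thermodynamic driving force,
regulation).  Without measured kcat values the condition-specific apparent
catalytic rate

    k_app^C = v^C / E^C

is used instead, its maximum over conditions k_app^max serving as an in vivo
kcat proxy, so that eta^C = k_app^C / k_app^max = v^C / (E^C * k_app^max).

The flux-sum of a metabolite, phi_i = sum_j max(S_ij, 0) * v_j, is the total
production turnover of the metabolite and is used as a proxy for its
concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flux_estimation import FluxDistribution
from .model_io import MetabolicModel, producer_matrix

__all__ = [
    "ConditionDataset",
    "KineticTable",
    "compute_kapp",
    "compute_kapp_table",
    "compute_kappmax",
    "compute_eta",
    "compute_flux_sums",
    "compute_flux_sum_table",
    "build_kinetic_table",
    "read_wide_table",
    "write_wide_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionDataset:
    """Matched enzyme abundances and fluxes across experimental conditions.

    ``enzyme_abundance`` and ``flux`` are wide tables indexed by reaction id
    with one column per condition; NaN marks missing measurements.  Biological
    replicates of one strain share a ``replicate_group`` key, so that
    cross-validation can keep them on the same side of a fold split.
    """

    condition_ids: list[str]
    replicate_group: pd.Series  # condition_id -> group key
    enzyme_abundance: pd.DataFrame  # reactions x conditions (mmol gDW^-1)
    flux: pd.DataFrame  # reactions x conditions (mmol gDW^-1 h^-1)

    def __post_init__(self) -> None:
        missing = [c for c in self.condition_ids if c not in self.replicate_group.index]
        if missing:
            raise ValueError(f"conditions missing from replicate manifest: {missing}")
        for name, df in (("enzyme_abundance", self.enzyme_abundance), ("flux", self.flux)):
            extra = [c for c in df.columns if c not in set(self.condition_ids)]
            if extra:
                raise ValueError(f"{name} has columns not in condition_ids: {extra}")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"{name} contains negative values")

    @property
    def groups(self) -> pd.Series:
        return self.replicate_group.loc[self.condition_ids]


@dataclass
class KineticTable:
    """Per-reaction apparent catalytic rates and concentration effects.

    Invariants: ``kapp_max`` is the row-wise maximum of ``kapp`` over defined
    conditions, ``eta = kapp / kapp_max`` where both are defined, and every
    reaction attains ``eta == 1`` in at least one condition.
    """

    kapp: pd.DataFrame  # reactions x conditions (h^-1)
    kapp_max: pd.Series  # per reaction (h^-1)
    eta: pd.DataFrame  # reactions x conditions, values in (0, 1]
    dropped_reactions: list[str] = field(default_factory=list)


def compute_kapp(flux: FluxDistribution | pd.Series, abundance: pd.Series) -> pd.Series:
    """Apparent catalytic rate k_app = v / E per reaction (h^-1).

    Reactions with missing or zero abundance get NaN (explicitly missing,
    never zero — a zero would corrupt the k_app^max proxy downstream).
    """
    v = flux.values if isinstance(flux, FluxDistribution) else flux
    if (abundance.dropna() < 0).any():
        bad = abundance[abundance < 0].index.tolist()
        raise ValueError(f"negative enzyme abundance for: {bad}")
    common = v.index.intersection(abundance.index)
    E = abundance.loc[common]
    denom = E.where(E > 0)  # zero abundance -> NaN
    return (v.loc[common] / denom).rename("kapp")


def compute_kapp_table(dataset: ConditionDataset) -> pd.DataFrame:
    """k_app per (reaction, condition) from matched flux/abundance tables."""
    common = dataset.flux.index.intersection(dataset.enzyme_abundance.index)
    E = dataset.enzyme_abundance.loc[common, dataset.condition_ids]
    V = dataset.flux.loc[common, dataset.condition_ids]
    return V / E.where(E > 0)


def compute_kappmax(kapp: pd.DataFrame) -> pd.Series:
    """Per-reaction maximum of k_app over all conditions with defined values.

    Reactions with no defined k_app anywhere are excluded (and logged), not
    errors.
    """
    defined = kapp.notna().any(axis=1)
    dropped = kapp.index[~defined].tolist()
    if dropped:
        logger.info("compute_kappmax: excluding %d reaction(s) with no defined k_app: %s",
                    len(dropped), dropped)
    return kapp.loc[defined].max(axis=1, skipna=True).rename("kapp_max")


def compute_eta(
    kapp: pd.DataFrame, kappmax: pd.Series, clip_range: bool = False
) -> pd.DataFrame:
    """Metabolite concentration effects eta = k_app / k_app^max.

    When ``kappmax`` derives from the same table the result is guaranteed in
    [0, 1].  With an external k_app^max source (transfer scenarios) entries
    can exceed 1; pass ``clip_range=True`` to mask values outside (0, 1]
    as missing (they are excluded from training data).
    """
    if (kappmax.dropna() <= 0).any():
        bad = kappmax[kappmax <= 0].index.tolist()
        raise ValueError(f"k_app^max must be positive; offending reactions: {bad}")
    common = kapp.index.intersection(kappmax.index)
    eta = kapp.loc[common].div(kappmax.loc[common], axis=0)
    if clip_range:
        n_out = int(((eta > 1) | (eta <= 0)).sum().sum())
        if n_out:
            logger.info("compute_eta: masking %d entries outside (0, 1]", n_out)
        eta = eta.where((eta > 0) & (eta <= 1))
    return eta


def build_kinetic_table(
    dataset: ConditionDataset, kappmax_override: pd.Series | None = None
) -> KineticTable:
    """k_app, k_app^max and eta in one pass from a condition dataset.

    ``kappmax_override`` replaces internally computed maxima (the transfer
    scenario: models trained on one data set, capacities from another); eta
    entries falling outside (0, 1] under the override are masked.
    """
    kapp = compute_kapp_table(dataset)
    kappmax = compute_kappmax(kapp)
    dropped = [r for r in kapp.index if r not in kappmax.index]
    if kappmax_override is not None:
        kappmax = kappmax_override.loc[kappmax_override.index.intersection(kapp.index)]
        eta = compute_eta(kapp, kappmax, clip_range=True)
    else:
        eta = compute_eta(kapp, kappmax)
    return KineticTable(
        kapp=kapp.loc[kappmax.index],
        kapp_max=kappmax,
        eta=eta,
        dropped_reactions=dropped,
    )


# ---------------------------------------------------------------------------
# flux-sums
# ---------------------------------------------------------------------------

def compute_flux_sums(model: MetabolicModel, flux: FluxDistribution | pd.Series) -> pd.Series:
    """Flux-sum phi_i = sum_j S+_ij v_j per metabolite (production turnover)."""
    v = flux.values if isinstance(flux, FluxDistribution) else flux
    if len(v) != model.n_reactions:
        raise ValueError(
            f"flux vector has {len(v)} entries, model has {model.n_reactions} reactions"
        )
    vec = v.reindex(model.reaction_ids).to_numpy(dtype=float)
    if np.isnan(vec).any():
        raise ValueError("flux vector does not cover all model reactions")
    phi = producer_matrix(model) @ vec
    return pd.Series(phi, index=model.metabolite_ids, name="phi")


def compute_flux_sum_table(model: MetabolicModel, flux_table: pd.DataFrame) -> pd.DataFrame:
    """Flux-sums per (metabolite, condition) for a wide reactions x conditions table."""
    V = flux_table.reindex(model.reaction_ids).to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValueError("flux table does not cover all model reactions")
    Phi = producer_matrix(model) @ V
    return pd.DataFrame(Phi, index=model.metabolite_ids, columns=flux_table.columns)


# ---------------------------------------------------------------------------
# delimited-text interfaces (wide layout: id column + one column per condition)
# ---------------------------------------------------------------------------

def read_wide_table(path: str, sep: str = "\t", index_name: str = "reaction_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if index_name not in df.columns:
        raise ValueError(f"{path!r} must have an {index_name!r} column")
    return df.set_index(index_name)


def write_wide_table(df: pd.DataFrame, path: str, sep: str = "\t",
                     index_name: str = "reaction_id") -> None:
    df.rename_axis(index_name).to_csv(path, sep=sep)
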