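"""Loading, validation and irreversible conversion of genome-scale metabolic models.

A :class:`MetabolicModel` is a light-weight stoichiometric container: a sparse
stoichiometric matrix ``S`` (metabolites x reactions), flux bounds, subsystem
labels and gene-reaction rules.  Models can be read from SBML (Level 3 + FBC,
via cobrapy) or from a small JSON dialect used for desk-scale fixtures::

    {"metabolites": [{"id": "A"}, ...],
     "reactions":   [{"id": "R1", "stoich": {"A": -1, "B": 1},
                      "lb": 0, "ub": 1000,
                      "subsystem": "Glycolysis", "gene_rule": "b0001"}, ...],
     "objective":   "R_biomass"}

All downstream analysis operates on the irreversible form of the network, in
which every reversible reaction ``R`` is split into a forward copy ``R_f``
(original column) and a backward copy ``R_b`` (negated column), both with
non-negative flux bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicModel",
    "ModelFormatError",
    "ModelValidationError",
    "load_model",
    "save_model_json",
    "make_irreversible",
    "producer_matrix",
]


class ModelFormatError(ValueError):
    """The model file could not be parsed as the declared format."""


class ModelValidationError(ValueError):
    """The parsed model violates a structural invariant."""


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds and annotations.

    Attributes
    ----------
    reaction_ids, metabolite_ids
        Stable string identifiers; matrix columns/rows follow this order.
    S
        Sparse stoichiometric matrix, shape ``(n_metabolites, n_reactions)``.
    lower_bounds, upper_bounds
        Flux bounds per reaction (mmol gDW^-1 h^-1).
    subsystems
        One label per reaction; missing annotations map to ``""``.
    gene_rules
        Raw gene-reaction association strings (not interpreted here).
    objective_reaction
        Identifier of the biomass/growth reaction, or ``None``.
    split_map
        After irreversible conversion, maps each reaction id to
        ``(original_id, sign)`` where sign is +1 for forward and -1 for
        backward copies.  Identity mapping for natively irreversible models.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    subsystems: list[str]
    gene_rules: list[str]
    objective_reaction: str | None = None
    irreversible: bool = False
    split_map: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        n_m, n_r = self.S.shape
        if len(self.reaction_ids) != n_r or len(self.metabolite_ids) != n_m:
            raise ModelValidationError(
                f"dimension mismatch: S is {n_m}x{n_r} but got "
                f"{len(self.metabolite_ids)} metabolites / {len(self.reaction_ids)} reactions"
            )
        for name, seq, n in (
            ("lower_bounds", self.lower_bounds, n_r),
            ("upper_bounds", self.upper_bounds, n_r),
            ("subsystems", self.subsystems, n_r),
            ("gene_rules", self.gene_rules, n_r),
        ):
            if len(seq) != n:
                raise ModelValidationError(f"{name} has length {len(seq)}, expected {n}")
        dupes = _duplicates(self.reaction_ids)
        if dupes:
            raise ModelValidationError(f"duplicated reaction identifier(s): {sorted(dupes)}")
        dupes = _duplicates(self.metabolite_ids)
        if dupes:
            raise ModelValidationError(f"duplicated metabolite identifier(s): {sorted(dupes)}")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = [self.reaction_ids[i] for i in np.flatnonzero(self.lower_bounds > self.upper_bounds)]
            raise ModelValidationError(f"lower bound exceeds upper bound for: {bad}")

    # -- convenience -----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Boolean flag per reaction: can the flux be negative?"""
        return self.lower_bounds < 0

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[rid]

    def metabolite_index(self, mid: str) -> int:
        try:
            return self._met_index[mid]
        except AttributeError:
            self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
            return self._met_index[mid]

    def substrates_of(self, rid: str) -> list[str]:
        """Metabolites consumed by a reaction (negative stoichiometry)."""
        col = self.S.getcol(self.reaction_index(rid)).tocoo()
        return [self.metabolite_ids[i] for i, v in zip(col.row, col.data) if v < 0]

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            subsystems=list(self.subsystems),
            gene_rules=list(self.gene_rules),
            split_map=dict(self.split_map),
        )


def _duplicates(seq: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in seq:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Load a metabolic model from SBML or the JSON fixture dialect.

    Parameters
    ----------
    path
        File path.  When *format* is ``None`` it is inferred from the
        extension (``.xml``/``.sbml`` -> sbml, ``.json`` -> json).
    """
    if format is None:
        lower = str(path).lower()
        format = "sbml" if lower.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}; expected 'sbml' or 'json'")


def _load_json(path: str) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON: {exc}") from exc
    try:
        met_ids = [m["id"] for m in doc["metabolites"]]
        rxns = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"missing required element: {exc}") from exc
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    rxn_ids, lbs, ubs, subs, rules = [], [], [], [], []
    for j, r in enumerate(rxns):
        try:
            rxn_ids.append(r["id"])
            for met, coeff in r["stoich"].items():
                if met not in met_index:
                    raise ModelFormatError(
                        f"reaction {r['id']!r} references unknown metabolite {met!r}"
                    )
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coeff))
            lbs.append(float(r["lb"]))
            ubs.append(float(r["ub"]))
        except KeyError as exc:
            raise ModelFormatError(f"reaction entry {j} missing field {exc}") from exc
        subs.append(r.get("subsystem") or "")
        rules.append(r.get("gene_rule") or "")
    S = sp.coo_matrix((data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))).tocsc()
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        subsystems=subs,
        gene_rules=rules,
        objective_reaction=doc.get("objective"),
    )


def _load_sbml(path: str) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises a zoo of exception types
        raise ModelFormatError(f"could not parse SBML file {path!r}: {exc}") from exc
    met_ids = [m.id for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    rxn_ids, lbs, ubs, subs, rules = [], [], [], [], []
    objective = None
    for j, r in enumerate(cm.reactions):
        rxn_ids.append(r.id)
        for met, coeff in r.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coeff))
        lbs.append(float(r.lower_bound))
        ubs.append(float(r.upper_bound))
        subs.append(r.subsystem or "")
        rules.append(r.gene_reaction_rule or "")
        if r.objective_coefficient:
            objective = r.id
    S = sp.coo_matrix((data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))).tocsc()
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        S=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        subsystems=subs,
        gene_rules=rules,
        objective_reaction=objective,
    )


def save_model_json(model: MetabolicModel, path: str) -> None:
    """Write the model to the JSON dialect losslessly (bounds, S, annotations)."""
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        stoich = {model.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}
        reactions.append(
            {
                "id": rid,
                "stoich": stoich,
                "lb": float(model.lower_bounds[j]),
                "ub": float(model.upper_bounds[j]),
                "subsystem": model.subsystems[j],
                "gene_rule": model.gene_rules[j],
            }
        )
    doc = {
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "reactions": reactions,
        "objective": model.objective_reaction,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Irreversible conversion
# ---------------------------------------------------------------------------

def make_irreversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction into forward (``_f``) and backward (``_b``) copies.

    The forward copy keeps the original column with bounds ``[max(lb, 0), ub]``;
    the backward copy gets the negated column with bounds ``[0, -lb]``.
    Irreversible reactions pass through unchanged.  Idempotent: applying the
    conversion to an already irreversible model returns an equal model with an
    identity ``split_map``.
    """
    S = model.S.tocsc()
    cols = []
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    subs: list[str] = []
    rules: list[str] = []
    split_map: dict[str, tuple[str, int]] = {}
    objective = model.objective_reaction
    for j, rid in enumerate(model.reaction_ids):
        lb, ub = model.lower_bounds[j], model.upper_bounds[j]
        if lb > ub:
            raise ModelValidationError(f"reaction {rid!r} has lb > ub ({lb} > {ub})")
        col = S.getcol(j)
        if lb < 0:
            fid, bid = rid + "_f", rid + "_b"
            cols.append(col)
            rxn_ids.append(fid)
            lbs.append(0.0)
            ubs.append(max(ub, 0.0))
            subs.append(model.subsystems[j])
            rules.append(model.gene_rules[j])
            split_map[fid] = (rid, +1)
            cols.append(-col)
            rxn_ids.append(bid)
            lbs.append(0.0)
            ubs.append(-lb)
            subs.append(model.subsystems[j])
            rules.append(model.gene_rules[j])
            split_map[bid] = (rid, -1)
            if objective == rid:
                objective = fid
        else:
            cols.append(col)
            rxn_ids.append(rid)
            lbs.append(lb)
            ubs.append(ub)
            subs.append(model.subsystems[j])
            rules.append(model.gene_rules[j])
            split_map[rid] = (rid, +1)
    return MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=list(model.metabolite_ids),
        S=sp.hstack(cols, format="csc") if cols else sp.csc_matrix((model.n_metabolites, 0)),
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        subsystems=subs,
        gene_rules=rules,
        objective_reaction=objective,
        irreversible=True,
        split_map=split_map,
    )


def producer_matrix(model: MetabolicModel) -> sp.csc_matrix:
    """Return S+ with entries ``max(S_ij, 0)`` (production-side stoichiometry)."""
    S = model.S.tocsc(copy=True)
    S.data = np.maximum(S.data, 0.0)
    S.eliminate_zeros()
    return S
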