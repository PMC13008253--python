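import json

import numpy as np
import pytest

from kineflux.eta_regression import EtaModel
from kineflux.synthetic import generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default noiseless fixture: 25 reactions, 30 conditions, 15 groups."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def bundle_hiflux():
    """Same study at high flux scale, where the total-flux term is negligible."""
    return generate_bundle(seed=1, flux_scale=1000.0)


def exact_eta_models(bundle):
    """EtaModels carrying the generator's own coefficients (oracle models)."""
    truth = bundle.truth
    models = {}
    for r in bundle.kinetic_reactions:
        al = truth.alpha[r]
        sub = "S" + r[-2:]
        models[r] = EtaModel(
            reaction_id=r,
            substrate_metabolites=(sub,),
            extra_metabolites=tuple(k for k in al if k != sub),
            alpha={k: float(v) for k, v in al.items()},
            beta=float(truth.beta[r]),
            cv_adj_r2=1.0,
            n_train=len(bundle.dataset.condition_ids),
        )
    return models


@pytest.fixture(scope="session")
def oracle_models(bundle_hiflux):
    return exact_eta_models(bundle_hiflux)


def write_json_model(path, metabolites, reactions, objective=None):
    doc = {
        "metabolites": [{"id": m} for m in metabolites],
        "reactions": reactions,
        "objective": objective,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)


@pytest.fixture
def chain_model_path(tmp_path):
    """UPT -> A -> B -> C -> SINK, all irreversible."""
    reactions = [
        {"id": "UPT", "stoich": {"A": 1}, "lb": 0, "ub": 1000, "subsystem": "Transport"},
        {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 1000, "subsystem": "Chain"},
        {"id": "R2", "stoich": {"B": -1, "C": 1}, "lb": 0, "ub": 1000, "subsystem": "Chain"},
        {"id": "SINK", "stoich": {"C": -1}, "lb": 0, "ub": 1000, "subsystem": "Biomass"},
    ]
    return write_json_model(tmp_path / "chain.json", ["A", "B", "C"], reactions, "SINK")


@pytest.fixture(autouse=True)
def _seeded_numpy():
    np.random.seed(0)
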