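"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest
from hypothesis import settings

from mma.model_io import MetabolicModel, Metabolite, Reaction, identity_compartment_map
from mma.pipeline import partition_model, ssm_workflow
from mma.synthetic import SyntheticSpec, plant_and_measure, toy_model

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_model(reactions, metabolite_ids, name="test", excluded=()):
    """Terse model builder: reactions as (id, reversible, reactants, products)."""
    mets = tuple(
        Metabolite(
            node_id=m,
            base_name=m.split("[")[0],
            compartment=m.split("[")[1].rstrip("]") if "[" in m else "",
            excluded=m in excluded or m.split("[")[0] in excluded,
        )
        for m in metabolite_ids
    )
    rxns = tuple(
        Reaction(rid, rev, dict(reac), dict(prod)) for rid, rev, reac, prod in reactions
    )
    return MetabolicModel(name=name, reactions=rxns, metabolites=mets)


@pytest.fixture(scope="session")
def toy():
    """The five-reaction worked-example fixture and its SSM node set."""
    return toy_model()


@pytest.fixture(scope="session")
def planted_run():
    """One full pipeline run on the default planted synthetic spec."""
    spec = SyntheticSpec(seed=0)
    model, data, truth = plant_and_measure(spec)
    cmap = identity_compartment_map(model)
    table = ssm_workflow(data, model, cmap, "0h", "3h", method="exact")
    result = partition_model(model, table.ssm_nodes, weighted=True)
    return spec, model, data, truth, table, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
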