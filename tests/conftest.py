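import numpy as np
import pytest

from abkinetics import (
    KineticParams,
    ModelConfig,
    build_complete_model,
    build_full_pathway_model,
    build_lateral_model,
    build_simple_model,
)


@pytest.fixture(scope="session")
def params():
    """Best-fit elongation/lateral constants with default mapping scales."""
    return KineticParams()


@pytest.fixture(scope="session")
def simple_model():
    return build_simple_model()


@pytest.fixture(scope="session")
def complete_model():
    return build_complete_model()


@pytest.fixture(scope="session")
def lateral_model():
    return build_lateral_model()


@pytest.fixture(scope="session")
def pathway_model():
    return build_full_pathway_model(n=6, max_size=20)


@pytest.fixture(scope="session")
def all_models(simple_model, complete_model, lateral_model, pathway_model):
    return [simple_model, complete_model, lateral_model, pathway_model]


@pytest.fixture(scope="session")
def tiny_chain():
    """5-species monomer-addition chain (A1, F, F1..F3) for oracle checks."""
    return build_simple_model(ModelConfig(max_elongation=3, lateral_coupling_count=0))


def random_states(model, n=100, scale=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((n, model.n_species)) * scale
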