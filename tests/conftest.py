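import numpy as np
import pytest

from metaweb import (
    ModelParams,
    Species,
    make_fixture,
    run_ecology,
)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def chain_state():
    """Single patch, resource -> A -> B, freshly built."""
    return make_fixture("single-patch-chain")


@pytest.fixture(scope="session")
def relaxed_chain():
    """Chain fixture after 100 ecological steps (near quasi-equilibrium)."""
    state = make_fixture("single-patch-chain")
    run_ecology(state, 100)
    return state


@pytest.fixture()
def subsidy_state():
    return make_fixture("two-patch-subsidy")


@pytest.fixture(scope="session")
def seeded_grid():
    """Small assembled 3x3 meta-community at a fixed seed."""
    return make_fixture("grid-3x3-seeded")


@pytest.fixture()
def playground():
    """Empty 6x6 resources-only meta-network."""
    return make_fixture("invasion-playground")


def make_species(sid, traits, bodysize, is_resource=False):
    return Species(id=sid, traits=frozenset(traits), bodysize=bodysize,
                   is_resource=is_resource)
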