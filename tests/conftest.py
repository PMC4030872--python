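"""Shared fixtures.

Expensive objects (the converged double-well weight, synthetic ensembles)
are session-scoped and shared across test modules; everything is seeded,
so the whole suite is deterministic.
"""

import numpy as np
import pytest

from mcfold.sampler import SamplerParams
from mcfold.structure_io import RegionSpec
from mcfold.synthetic import SyntheticConfig, make_reference_models, sample_ensemble
from mcfold.toy_systems import make_chain_model, make_double_well, make_harmonic
from mcfold.weights import ProtocolSchedule, iterate_weights


@pytest.fixture(scope="session")
def double_well():
    """Tilted double well: barrier 1 kcal/mol, wells near x = +-1."""
    return make_double_well(1.0, 0.2)


@pytest.fixture(scope="session")
def harmonic2():
    return make_harmonic(2, 1.0)


@pytest.fixture(scope="session")
def chain8():
    return make_chain_model(8, 1.0)


@pytest.fixture(scope="session")
def dw_params():
    return SamplerParams(
        dt=0.01,
        T_sim=700.0,
        friction=1.0,
        n_steps=60_000,
        sample_every=10,
        seed=1,
        wall_stiffness=0.25,
    )


@pytest.fixture(scope="session")
def dw_protocol(double_well, dw_params):
    """Converged weight, iteration report and final run on the double well."""
    schedule = ProtocolSchedule(max_iterations=12, n_traj=6)
    return iterate_weights(double_well, schedule, dw_params)


@pytest.fixture(scope="session")
def regions():
    return RegionSpec(chain_id="B")


@pytest.fixture(scope="session")
def synth_config():
    return SyntheticConfig(n_conformations=400, seed=3)


@pytest.fixture(scope="session")
def reference_models(synth_config):
    return make_reference_models(synth_config)


@pytest.fixture(scope="session")
def synthetic_ensemble(synth_config):
    """(conformations, truth record) for the default 400-member ensemble."""
    return sample_ensemble(synth_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
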