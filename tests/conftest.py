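"""Shared fixtures: codebooks, simulated stacks, and a trained predictor.

Expensive artifacts (simulation, classifier training, a decoded run) are
session-scoped so the whole suite pays for them once.
"""

import pytest
from hypothesis import settings

from issgraph import SimConfig, simulate_iss

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from issgraph.pipeline import (DecodeConfig, decode_stack,
                               train_model_from_simulation)
from issgraph.simdata import balanced_codebook, fig1a_fixture


@pytest.fixture(scope="session")
def codebook8():
    return balanced_codebook(8, n_cycles=4, seed=0)


@pytest.fixture(scope="session")
def sim_stack(codebook8):
    """One simulated stack at the default study conditions (seed 42)."""
    return simulate_iss(SimConfig(seed=42), codebook8)


@pytest.fixture(scope="session")
def trained_model(codebook8):
    """Probability model trained on an independent simulated stack."""
    return train_model_from_simulation(SimConfig(seed=0), codebook8, seed=0)


@pytest.fixture(scope="session")
def decoded_run(sim_stack, codebook8, trained_model):
    """Full pipeline output on the seed-42 stack."""
    stack, truth = sim_stack
    result = decode_stack(stack, codebook8, trained_model, DecodeConfig())
    return stack, truth, result


@pytest.fixture()
def fig1a():
    return fig1a_fixture()
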