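"""Shared fixtures: small chain models and one cached reference simulation."""

import warnings

import numpy as np
import pytest

from excinet.engine import StimulusSpec, run
from excinet.network import build_chain
from excinet.workbench import chain_model

warnings.filterwarnings("ignore", category=RuntimeWarning, module="excinet")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_chain():
    """Six-group excitatory-only chain at a mid-range weight."""
    return chain_model(variant="exc_only", n_groups=6, w_exc_psp=0.35, seed=11)


@pytest.fixture(scope="session")
def small_chain_run(small_chain):
    """One simulated trial of the small chain (stimulus on assembly 1)."""
    return run(
        small_chain,
        [StimulusSpec(target="exc_1")],
        T=700.0,
        dt=0.1,
        seed=101,
    )


@pytest.fixture(scope="session")
def inh_chain():
    """Six-group chain with one inhibitory population per group."""
    return chain_model(
        variant="exc_inh", n_groups=6, w_exc_psp=0.40, w_inh_psp=0.30, seed=11
    )


@pytest.fixture(scope="session")
def tiny_exc_pair():
    """Two isolated assemblies (no inter-group weight) for burst tests."""
    return build_chain(n_groups=2, w_exc=0.0, variant="exc_only", seed=5)
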