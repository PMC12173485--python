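"""Shared fixtures: small deterministic flow states and populations."""

import numpy as np
import pytest

from microswim import FlowParams, SwimmerPopulation, init_flow


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_flow():
    """One synthetic flow realization with the default parameters."""
    return init_flow(FlowParams(seed=42))


def make_population(n, us, alpha, L=2 * np.pi, seed=0, tau_0=1.0):
    return SwimmerPopulation.random(n, us, alpha, L, np.random.default_rng(seed),
                                    tau_0=tau_0)
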