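"""Shared fixtures.

Small networks back the fast unit tests; the session-scoped fixtures run the
production-size rivalry configuration once and are shared by the acceptance
tests (network building and simulation are deterministic given the seed).
"""

import numpy as np
import pytest

from rivalnet import (ModelParams, RFParams, build_network, make_grating,
                      normalize_stimulus, simulate)
from rivalnet.experiments import run_rivalry


@pytest.fixture(scope="session")
def small_params():
    """A fast 120-neuron-per-pool configuration for unit tests."""
    return ModelParams(N_E=60, N_I=60, K=8, n_pixels=100)


@pytest.fixture(scope="session")
def small_network(small_params):
    return build_network(small_params, seed=123)


@pytest.fixture(scope="session")
def small_stimuli(small_params):
    img1 = normalize_stimulus(make_grating(10, "horizontal", 4), 0.5)
    img2 = normalize_stimulus(make_grating(10, "vertical", 4), 0.5)
    return img1, img2


@pytest.fixture(scope="session")
def small_sim(small_network, small_stimuli, small_params):
    return simulate(small_network, small_stimuli, small_params, 2000.0,
                    seed=7, record_spikes=True)


@pytest.fixture(scope="session")
def rivalry_run_40s():
    """Production-size rivalry run: default parameters, gratings, 40 s."""
    return run_rivalry(ModelParams(), duration=40000.0, seed=1)


@pytest.fixture(scope="session")
def rivalry_reconstructions(rivalry_run_40s):
    from rivalnet.reconstruction import reconstruct_run

    run = rivalry_run_40s
    return reconstruct_run(run.sim, run.network, run.segments, run.params,
                           truths=run.stimuli)
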