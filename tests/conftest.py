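"""Shared fixtures: reference parameter set and cached reference simulations."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from minwave import (
    REFERENCE_DIFFUSION,
    REFERENCE_PARAMS,
    REFERENCE_TOTALS,
    SimulationConfig,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def diffusion():
    return REFERENCE_DIFFUSION


@pytest.fixture(scope="session")
def totals():
    return REFERENCE_TOTALS


@pytest.fixture(scope="session")
def reference_kymo_3um():
    """Full-resolution 140-s run of the reference set at L = 3.0 um.

    Session-scoped: this is the workhorse trajectory shared by the
    simulator, metrics, and acceptance tests.
    """
    cfg = SimulationConfig(length=3.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return simulate(REFERENCE_PARAMS, REFERENCE_DIFFUSION, cfg)


@pytest.fixture(scope="session")
def reference_kymos_all_lengths(reference_kymo_3um):
    """Reference-set runs at the four report lengths, keyed by length."""
    out = {3.0: reference_kymo_3um}
    for length in (2.6, 3.8, 4.6):
        cfg = SimulationConfig(length=length)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[length] = simulate(REFERENCE_PARAMS, REFERENCE_DIFFUSION, cfg)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
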