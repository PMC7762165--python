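"""Shared fixtures: reference parameter sets for a swelling hydrogel disc."""

import numpy as np
import pytest

from swellrelease import OnePhaseParams, SwellingParams, TwoPhaseParams

# Fitted kinetics of a 1-cm bacterial-cellulose hydrogel disc (device 307035):
# moderate swelling, slow first phase, ~4.6x faster second phase after 2 h.
REFERENCE_DEVICE = {
    "L": 5.0,            # mm (disc radius)
    "m": 2.0,            # assumed asymptotic swelling ratio
    "g": 1.17298e-4,     # 1/s
    "D": 8.58865e-4,     # mm^2/s, one-phase
    "D0": 3.25908e-4,    # mm^2/s, first phase
    "D1": 1.49489e-3,    # mm^2/s, second phase
    "tc": 7200.0,        # s
}

# Faster-swelling sibling formulation (device 208035)
FAST_DEVICE_G = 1.49918e-4  # 1/s


@pytest.fixture
def sw():
    d = REFERENCE_DEVICE
    return SwellingParams(L=d["L"], m=d["m"], g=d["g"])


@pytest.fixture
def one_phase():
    return OnePhaseParams(D=REFERENCE_DEVICE["D"])


@pytest.fixture
def two_phase():
    d = REFERENCE_DEVICE
    return TwoPhaseParams(D0=d["D0"], D1=d["D1"], tc=d["tc"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
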