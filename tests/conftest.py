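"""Shared fixtures: reference guides and simulated spectra.

Spectra are generated programmatically; session scope keeps the heavier
simulations to one run per test session.
"""

import pytest

from spacerms import preprocess, reference_sequence, simulate_msms
from spacerms.spectra import SimulationConfig, clean_config


@pytest.fixture(scope="session")
def grna_x():
    return reference_sequence("gRNA X")


@pytest.fixture(scope="session")
def grna_xa():
    return reference_sequence("gRNA XA")


@pytest.fixture(scope="session")
def grna_xb():
    return reference_sequence("gRNA XB")


@pytest.fixture(scope="session")
def grna_xc():
    return reference_sequence("gRNA XC")


@pytest.fixture(scope="session")
def grna_xd():
    return reference_sequence("gRNA XD")


@pytest.fixture(scope="session")
def grna_y():
    return reference_sequence("gRNA Y")


def simulate(components, seed=0, noiseless=False, **overrides):
    """Simulate and preprocess one averaged spectrum."""
    if noiseless:
        cfg = clean_config(tuple(components), seed=seed, **overrides)
        return preprocess([simulate_msms(cfg)], noise_floor=0.0)
    cfg = SimulationConfig(tuple(components), seed=seed, **overrides)
    return preprocess([simulate_msms(cfg)])


@pytest.fixture(scope="session")
def pure_x_clean(grna_x):
    return simulate([(grna_x, 1.0)], seed=101, noiseless=True)


@pytest.fixture(scope="session")
def pure_x_noisy(grna_x):
    return simulate([(grna_x, 1.0)], seed=7)
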