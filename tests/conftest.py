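import numpy as np
import pytest

from pumpmc import (
    KineticParameters,
    VolumeContext,
    build_network,
    explore,
)

ANALYSIS_VOLUME = 1e-20  # litres; the volume used throughout the study


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def ctx_ceiling():
    return VolumeContext(volume=ANALYSIS_VOLUME, rounding="ceiling")


@pytest.fixture(scope="session")
def ctx_nearest():
    return VolumeContext(volume=ANALYSIS_VOLUME, rounding="nearest")


@pytest.fixture(scope="session")
def net_ceiling(params, ctx_ceiling):
    return build_network(params, ctx_ceiling)


@pytest.fixture(scope="session")
def net_nearest(params, ctx_nearest):
    return build_network(params, ctx_nearest)


@pytest.fixture(scope="session")
def pump_ceiling(net_ceiling):
    """The calibrated 194-state chain (K_o = 61)."""
    return explore(net_ceiling)


@pytest.fixture(scope="session")
def pump_nearest(net_nearest):
    """The 188-state chain under nearest rounding (K_o = 60; depletion
    reachable)."""
    return explore(net_nearest)


@pytest.fixture(scope="session")
def net_small(params):
    """Pump network at 1e-21 l: 32 states, cheap for simulation tests."""
    return build_network(params, VolumeContext(volume=1e-21, rounding="ceiling"))
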