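import numpy as np
import pytest

from smsepi.events import SystemLimits
from smsepi.protocol import ci_params, design_epi_readout, build_protocol
from smsepi.simulator import (
    AcqNoiseModel,
    make_ball_phantom,
    make_coil_maps,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def limits():
    return SystemLimits()


@pytest.fixture(scope="session")
def ci_protocol():
    """Reduced geometry, one output volume, no dummies."""
    return ci_params(n_volumes=1, n_dummy=0)


@pytest.fixture(scope="session")
def ci_readout(ci_protocol, limits):
    return design_epi_readout(ci_protocol, limits)


@pytest.fixture(scope="session")
def ci_phantom(ci_protocol):
    return make_ball_phantom(ci_protocol)


@pytest.fixture(scope="session")
def ci_maps(ci_protocol, ci_phantom):
    return make_coil_maps(ci_protocol, 6, seed=1, phantom=ci_phantom)


@pytest.fixture(scope="session")
def ci_noiseless(ci_protocol, ci_readout, ci_phantom, ci_maps, limits):
    """(raw, cal) of the noiseless reduced-geometry acquisition."""
    return simulate_acquisition(
        ci_phantom, ci_maps, ci_protocol, ci_readout, AcqNoiseModel(), limits
    )


@pytest.fixture(scope="session")
def ci_sequence(ci_protocol, limits):
    return build_protocol(ci_protocol, limits)


@pytest.fixture(scope="session")
def ci_fullfourier(limits):
    """Full-Fourier variant used to isolate ghost behavior from partial-
    Fourier truncation ringing."""
    p = ci_params(n_volumes=1, n_dummy=0, partial_fourier=1.0, tr=0.24)
    ph = make_ball_phantom(p)
    maps = make_coil_maps(p, 6, seed=1, phantom=ph)
    ro = design_epi_readout(p, limits)
    return p, ph, maps, ro
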