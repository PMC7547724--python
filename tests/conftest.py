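import numpy as np
import pytest

from lovfret.photocycle import PhotocycleParams


@pytest.fixture
def mtq2_optones() -> PhotocycleParams:
    """mTurquoise2 nuclear-export construct (donor readout)."""
    return PhotocycleParams(
        sensitivity=162.0, relaxation_time=6.8, transfer_limit=0.189, mode="donor"
    )


@pytest.fixture
def ypet_optones() -> PhotocycleParams:
    """Ypet nuclear-export construct (acceptor readout)."""
    return PhotocycleParams(
        sensitivity=559.0, relaxation_time=8.0, transfer_limit=0.535, mode="acceptor"
    )


@pytest.fixture
def mtq2_optojnki() -> PhotocycleParams:
    return PhotocycleParams(sensitivity=206.0, relaxation_time=13.7,
                            transfer_limit=0.17, mode="donor")


@pytest.fixture
def ypet_optojnki() -> PhotocycleParams:
    return PhotocycleParams(sensitivity=843.0, relaxation_time=23.0,
                            transfer_limit=0.604, mode="acceptor")


@pytest.fixture
def mscarlet_optojnki() -> PhotocycleParams:
    return PhotocycleParams(sensitivity=1594.0, relaxation_time=15.5,
                            transfer_limit=0.688, mode="acceptor")
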