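import numpy as np
import pytest

from otopkin import (
    BinaryElement,
    ChannelModel,
    Conditions,
    otop3_zn_model,
)

RT = 0.593


@pytest.fixture(scope="session")
def model():
    """The built-in four-element Zn2+ potentiation/block model."""
    return otop3_zn_model()


@pytest.fixture(scope="session")
def pore_only():
    """Isolated pore gate (two-state closed/open model)."""
    return ChannelModel(
        (BinaryElement("pore", "gate", 0.02, 25.0, conducts_when_on=True),)
    )


@pytest.fixture(scope="session")
def blocker_only():
    """Pore plus the independent fast blocking site (no couplings)."""
    return ChannelModel(
        (
            BinaryElement("pore", "gate", 0.02, 25.0, conducts_when_on=True),
            BinaryElement("ZnB", "site", 5e4, 20.0, ligand="Zn",
                          blocks_when_on=True),
        )
    )


@pytest.fixture
def acid_conditions():
    return Conditions.from_ph_zn(5.5, 1e-3)


def checkpoints(n, size):
    return np.linspace(0, size - 1, n).astype(int)
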