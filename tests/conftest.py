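import numpy as np
import pytest

from eragate import (
    Alphabet,
    CrRNASpec,
    DuplexLayout,
    EnergyModel,
    NucleicSequence,
    RateParams,
    ToeholdDirection,
    reference_calibration,
)


@pytest.fixture(scope="session")
def crrna22():
    return CrRNASpec(NucleicSequence("ACGUACGUACGUACGUACGUAC", Alphabet.RNA,
                                     "spacer22"))


@pytest.fixture(scope="session")
def crrna35():
    return CrRNASpec(NucleicSequence("ACGUACGUACGUACGUACGUACGGAUCCGGAUCCG",
                                     Alphabet.RNA, "spacer35"))


@pytest.fixture(scope="session")
def energy():
    return EnergyModel()


@pytest.fixture(scope="session")
def rates():
    return RateParams()


@pytest.fixture(scope="session")
def calib():
    return reference_calibration()


@pytest.fixture(scope="session")
def layout_5p():
    """Factory for plain FIVE_PRIME layouts on a 22-nt spacer."""

    def make(f, r=0, era_mm=(), act_mm=()):
        return DuplexLayout(ToeholdDirection.FIVE_PRIME, f, r, 22 - f, 22,
                            era_mismatch_distances=tuple(era_mm),
                            activator_mismatch_distances=tuple(act_mm))

    return make


@pytest.fixture(scope="session")
def layout_3p():
    def make(f, r=0, era_mm=(), act_mm=()):
        return DuplexLayout(ToeholdDirection.THREE_PRIME, f, r, 22 - f, 22,
                            era_mismatch_distances=tuple(era_mm),
                            activator_mismatch_distances=tuple(act_mm))

    return make
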