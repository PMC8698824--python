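import pytest

from dzmatrix import (
    DesignConstraints,
    KineticParams,
    ReadoutConfig,
    StemConfig,
    design_four_pronged,
    design_matrix_library,
    design_three_pronged,
)


@pytest.fixture(scope="session")
def lib3():
    return design_three_pronged(DesignConstraints(
        stem_config=StemConfig.three_pronged_default(), seed=11))


@pytest.fixture(scope="session")
def lib4():
    return design_four_pronged(DesignConstraints(
        stem_config=StemConfig.four_pronged_default(), seed=11))


@pytest.fixture(scope="session")
def libw():
    return design_four_pronged(DesignConstraints(
        stem_config=StemConfig.weighted_default(), seed=11))


@pytest.fixture(scope="session")
def matlib22():
    return design_matrix_library(2, 2, 1, DesignConstraints(seed=11))


@pytest.fixture()
def params():
    return KineticParams()


@pytest.fixture()
def readout():
    return ReadoutConfig()
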