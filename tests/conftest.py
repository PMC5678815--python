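import pytest

from rilfkit import FiModelFit

# Published sigmoid parameters of the two fractionation arms (A = 7.20,
# ED50 in Gy, gamma dimensionless); used throughout as known truths.
ED50_1FX, GAMMA_1FX = 14.55, 1.64
ED50_5FX, GAMMA_5FX = 27.7, 1.41
SATURATION = 7.20


@pytest.fixture(scope="session")
def fit_1fx() -> FiModelFit:
    return FiModelFit(a=SATURATION, ed50=ED50_1FX, gamma=GAMMA_1FX)


@pytest.fixture(scope="session")
def fit_5fx() -> FiModelFit:
    return FiModelFit(a=SATURATION, ed50=ED50_5FX, gamma=GAMMA_5FX)
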