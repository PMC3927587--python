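import numpy as np
import pytest

from yeastabm import PhysiologyParams, StrainParams


@pytest.fixture
def phys():
    return PhysiologyParams()


@pytest.fixture
def strain():
    return StrainParams(strain_id="wt", ec_Tsl1=0.1e-6, ea_Tsl1=3.0e-6,
                        K_Tsl1=0.2, fr_Tsl1_cv=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
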