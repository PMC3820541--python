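import numpy as np
import pytest

from phosphorelay.core_model import ParameterSet, topology_by_id


@pytest.fixture(scope="session")
def t14():
    return topology_by_id(14)


@pytest.fixture(scope="session")
def t30():
    return topology_by_id(30)


@pytest.fixture(scope="session")
def tuning_params():
    """Reference tuning-regime instance of topology 30: strong REC
    hydrolysis and reverse-dominant REC-Hpt exchange give a sigmoidal
    curve with a low maximal response."""
    return ParameterSet(k_2=5, k_3=0.1, k_4=0.01, k_2r=0, k_3r=10,
                        k_4r=0.10, k_h1=10, k_h2=0.001,
                        HK_tot=5, REC_tot=1, Hpt_tot=1, RR_tot=10)


@pytest.fixture(scope="session")
def bif_regime_params():
    """Reference bifunctional-regime instance: fast bimolecular transfer
    rates at sub-millimolar totals, with HK binding/catalysis rates set;
    the monofunctional analysis ignores k_5/k_5r/k_6."""
    return ParameterSet(k_2=9343, k_3=30201, k_4=35826, k_2r=0, k_3r=7192,
                        k_4r=99251, k_h1=0.0302, k_h2=0.00234,
                        k_5=1000, k_5r=0.012, k_6=3.5,
                        HK_tot=1.2748e-04, REC_tot=1.5755e-04,
                        Hpt_tot=1.3634e-04, RR_tot=1.2516e-04)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
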