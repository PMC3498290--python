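import numpy as np
import pytest

from pherokin import synthetic as syn
from pherokin.kinetics import KineticParameters


@pytest.fixture
def batch_params() -> KineticParameters:
    """Apparent batch constants of the acetyl transferase."""
    return KineticParameters(km=syn.BATCH_KM_UM, vmax=syn.BATCH_VMAX_PKAT, vmax_unit="pKat")


@pytest.fixture
def ref_kinetics() -> KineticParameters:
    return syn.REFERENCE_KINETICS


@pytest.fixture
def ref_immo():
    return syn.REFERENCE_IMMOBILIZATION


@pytest.fixture
def substrate_levels() -> np.ndarray:
    return syn.default_substrate_levels()
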