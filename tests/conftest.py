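import numpy as np
import pytest

from braincm import BloodParams, CSFParams, TissueParams


@pytest.fixture
def blood():
    """Blood pool in the middle of the physiological range."""
    return BloodParams(c_in=0.05, k_out=0.03, hct=0.45)


@pytest.fixture
def tissue():
    """Tissue voxel with intact-BBB-scale transfer rates."""
    return TissueParams(
        k_trans=5e-4, k_ep=0.01, k_pi=2e-3, k_ip=5e-3,
        v_blood=0.05, v_ees=0.20, v_ies=0.72, v_now=0.03,
    )


@pytest.fixture
def csf():
    return CSFParams(k_in_prime=0.06, k_out_prime=0.03, v_blood=0.15, v_csf=0.85)


@pytest.fixture
def grid():
    """Default acquisition grid: 0-60 min, 1-min frames."""
    return np.linspace(0.0, 60.0, 61)


def max_rel_err(a, b):
    """max |a-b| / max|b| — curve-level relative error."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.max(np.abs(a - b)) / np.max(np.abs(b)))
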