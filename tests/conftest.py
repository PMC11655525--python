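import numpy as np
import pytest
from scipy.optimize import brentq

from azochrom import BindingParams, IsomerSpectra


@pytest.fixture(scope="session")
def pap_spectra() -> IsomerSpectra:
    return IsomerSpectra.default_pap()


def titration_oracle(
    params: BindingParams, V0, C0_pap, C0_cd, V_cd, path=1.0
) -> float:
    """Brute-force titration absorbance, independent of the closed form.

    Computes the diluted total guest/host concentrations, solves the
    mass-action law K_D = (P-b)(L-b)/b by numerical root bracketing on the
    physical branch 0 <= b <= min(P, L), and applies Beer-Lambert.
    """
    P = V0 * C0_pap / (V0 + V_cd)
    L = V_cd * C0_cd / (V0 + V_cd)
    if L == 0.0 or np.isinf(params.K_D):
        b = 0.0
    else:
        f = lambda b: (P - b) * (L - b) - params.K_D * b
        b = brentq(f, 0.0, min(P, L), xtol=1e-18, rtol=1e-15)
    return path * (params.eps_free * (P - b) + params.eps_bound * b)
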