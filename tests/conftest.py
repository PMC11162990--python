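import numpy as np
import pytest

from ngdwi.scheme import BValueScheme
from ngdwi.signals import (CTRWParams, DKIParams, FROCParams, IVIMParams,
                           MonoExpParams, SEMParams, signal_ctrw, signal_dki,
                           signal_froc, signal_ivim, signal_monoexp,
                           signal_sem)


@pytest.fixture(scope="session")
def scheme():
    """The default 11-b acquisition (0-2500 s/mm², δ=20 ms, Δ=40 ms)."""
    return BValueScheme()


#: representative in-bounds parameters for each model
TRUE_PARAMS = {
    "ADC": MonoExpParams(100.0, 1.0e-3),
    "IVIM": IVIMParams(100.0, 0.15, 1.0e-3, 15e-3),
    "DKI": DKIParams(100.0, 1.5e-3, 0.8),
    "SEM": SEMParams(100.0, 1.2e-3, 0.8),
    "FROC": FROCParams(100.0, 1.0e-3, 0.85, 5e-3),
    "CTRW": CTRWParams(100.0, 1.0e-3, 0.9, 0.9),
}

FORWARD = {
    "ADC": signal_monoexp,
    "IVIM": signal_ivim,
    "DKI": signal_dki,
    "SEM": signal_sem,
    "FROC": signal_froc,
    "CTRW": signal_ctrw,
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240609)
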