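import numpy as np
import pytest

from ivimnac import BValueScheme, IVIMParams, forward_signal

# Parameter triples of the two worked-example patients (internal units).
FIG1_PRE = IVIMParams(D=0.906e-3, D_star=40.4e-3, f=0.357, S0=1000.0)
FIG1_MID = IVIMParams(D=1.310e-3, D_star=13.8e-3, f=0.142, S0=1000.0)
FIG2_PRE = IVIMParams(D=1.110e-3, D_star=14.8e-3, f=0.292, S0=1000.0)
FIG2_MID = IVIMParams(D=1.410e-3, D_star=27.4e-3, f=0.214, S0=1000.0)

CASE_TRIPLES = {
    "fig1_pre": FIG1_PRE,
    "fig1_mid": FIG1_MID,
    "fig2_pre": FIG2_PRE,
    "fig2_mid": FIG2_MID,
}


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def noiseless_decay(params: IVIMParams, scheme: BValueScheme | None = None):
    return forward_signal(params, scheme or BValueScheme())
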