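import numpy as np
import pytest

from carueq import make_default_params
from carueq.params import LCCParams, RyRParams


@pytest.fixture
def small_params():
    """Wildtype constants on a small lattice for fast tests."""
    return make_default_params().with_grid(4, 4, 8)


@pytest.fixture
def tiny_params():
    return make_default_params().with_grid(2, 2, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def frozen_channel_params(params):
    """A variant whose channel transition rates are effectively zero, so the
    channel-state counts stay fixed and the dynamics are deterministic."""
    from dataclasses import replace

    z = 1e-300
    return replace(
        params,
        ryr_params=RyRParams(
            nu_open_max=z, k_close=z, nu_inact_max=z,
            k_i12=z, k_i21=z, k_i2c=z, k_i1o=z,
        ),
        lcc_params=LCCParams(
            g_lcc=params.lcc_params.g_lcc,
            alpha_max=z, beta_max=z, f_max=z, g_close=z,
            k_inact_max=z, r_recover=z, k_i12=z, k_i21=z,
            k_i2c2=z, k_c2i2=z,
        ),
    )
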