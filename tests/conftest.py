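import numpy as np
import pytest

import cryofil as cf


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_params():
    """Short curved protofilament-like chain for cheap force/energy tests."""
    return cf.FilamentParams(n_monomers=6, radius=2.0, bend_stiffness_b=58.0,
                             theta0=0.2, bond_stiffness_k=100.0, n_fixed=2)


@pytest.fixture
def straight_params():
    return cf.FilamentParams(n_monomers=8, radius=2.0, bend_stiffness_b=58.0,
                             theta0=0.0, bond_stiffness_k=100.0, n_fixed=1)


def perturbed_state(params, rng, scale=0.3):
    st = cf.straight_state(params)
    st.x += rng.normal(0, scale, st.n)
    st.y += rng.normal(0, scale, st.n)
    st.theta += rng.normal(0, scale, st.n)
    return st
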