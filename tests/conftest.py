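import numpy as np
import pytest

import cwfdual as cw
from cwfdual.kernels import make_kernel


@pytest.fixture(scope="session")
def fig1_coupled():
    return cw.fig1_model(coupled=True)


@pytest.fixture(scope="session")
def fig1_independent():
    return cw.fig1_model(coupled=False)


@pytest.fixture(scope="session")
def fig1_series_kernel(fig1_coupled):
    return make_kernel(fig1_coupled, "series_2x2")


@pytest.fixture(scope="session")
def fig1_quad_kernel(fig1_coupled):
    return make_kernel(fig1_coupled, "pim_quadrature")


@pytest.fixture(scope="session")
def one_locus_pim():
    """One locus, two alleles, asymmetric selection and mutation."""
    return cw.ModelSpec(M=(2,), h=[0.3, 0.7], J=None, pim_u=[[0.4, 0.9]])


def random_interior_x(spec, rng):
    return np.concatenate([rng.dirichlet(np.ones(m) * 2.0) for m in spec.M])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
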