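import numpy as np
import pytest

from vplct.decomposition import DecompositionBasis, decompose
from vplct.phantom import generate_default_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom96():
    """Default fibrotic phantom at production test scale (shared, read-only)."""
    spec = generate_default_spec(seed=1, grid_shape=(96, 96, 96))
    insp_low, insp_high, exp_low, exp_high, truth = generate_phantom(spec)
    return {
        "spec": spec,
        "insp_low": insp_low,
        "insp_high": insp_high,
        "exp_low": exp_low,
        "exp_high": exp_high,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def decomposed96(phantom96):
    basis = DecompositionBasis(phantom96["spec"].basis)
    vnc_i, pbv_i = decompose(phantom96["insp_low"], phantom96["insp_high"], basis)
    vnc_e, pbv_d = decompose(phantom96["exp_low"], phantom96["exp_high"], basis)
    return {"vnc_insp": vnc_i, "pbv_insp": pbv_i, "vnc_exp": vnc_e, "pbv_delayed": pbv_d}


@pytest.fixture(scope="session")
def registered_field96(phantom96, decomposed96):
    """The demons field for the 96-cube phantom (expensive; computed once)."""
    from vplct.registration import register

    return register(decomposed96["vnc_exp"], decomposed96["vnc_insp"], seed=0)


@pytest.fixture(scope="session")
def phantom48():
    """Small phantom for cheap structural tests."""
    spec = generate_default_spec(seed=3, grid_shape=(48, 48, 48))
    insp_low, insp_high, exp_low, exp_high, truth = generate_phantom(spec)
    return {
        "spec": spec,
        "insp_low": insp_low,
        "insp_high": insp_high,
        "exp_low": exp_low,
        "exp_high": exp_high,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
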