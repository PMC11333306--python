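"""Shared fixtures: the expensive artifacts (fitted transfer functions,
realized networks) are built once per session and reused across modules."""

import numpy as np
import pytest

import ca1mf


@pytest.fixture(scope="session")
def cells():
    return {"pyr": ca1mf.PYR_PARAMS, "fs": ca1mf.FS_PARAMS}


@pytest.fixture(scope="session")
def syn():
    return ca1mf.DEFAULT_SYN


@pytest.fixture(scope="session")
def reduced_top():
    """Desk-scale validation topology: 1,000 Pyr + 100 FS."""
    return ca1mf.reduced_topology()


@pytest.fixture(scope="session")
def tf_coeffs(reduced_top, cells, syn):
    """Balanced-ray transfer-function fits for both cell types."""
    return ca1mf.fit_transfer_functions(reduced_top, cells, syn,
                                        duration=40000.0, seeds=(10, 11))


@pytest.fixture(scope="session")
def mf_model(reduced_top, cells, syn, tf_coeffs):
    return ca1mf.model_from_topology(cells, tf_coeffs, reduced_top, syn)


@pytest.fixture(scope="session")
def graph(reduced_top):
    return ca1mf.build_network(reduced_top, seed=5)


@pytest.fixture(scope="session")
def slice_coeffs(cells, syn):
    """Transfer functions for the disinhibited slice regime."""
    return ca1mf.fit_slice_tf(ca1mf.NetworkTopology(), cells, syn, seed=20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
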