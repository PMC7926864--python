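"""Shared fixtures: small synthetic structures and their eigensystems."""

import numpy as np
import pytest

from modewire.enm import build_hessian, build_network, compute_modes
from modewire.synthetic import (
    _fcc_cluster,
    _model,
    make_dimer_transition_pair,
    make_hinge_dimer,
    make_symmetric_dimer_with_cochaperones,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.000  10.000  10.000  1.00 21.50           C
ATOM      3  CA  GLY A   2      14.500  10.200   9.800  1.00 30.00           C
ATOM      4  O   GLY A   2      15.000  11.000  10.000  1.00 15.00           O
ATOM      5  CA  SER A   3      18.100  10.500  10.300  1.00 12.25           C
END
"""

GAPPED_PDB = """\
ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C
ATOM      2  CA  ALA A   2      13.800  10.000  10.000  1.00 20.00           C
ATOM      3  CA  ALA A   4      17.600  10.000  10.000  1.00 20.00           C
END
"""


@pytest.fixture(scope="session")
def coil():
    """Compact 10-node blob: small, connected, well-conditioned spectrum."""
    rng = np.random.default_rng(4)
    return _model(_fcc_cluster(10, rng), ["A"] * 10)


@pytest.fixture(scope="session")
def coil_network(coil):
    return build_network(coil, rc=9.0)


@pytest.fixture(scope="session")
def coil_modes(coil_network):
    return compute_modes(build_hessian(coil_network))


@pytest.fixture(scope="session")
def hinge_pair():
    return make_hinge_dimer(seed=0)


@pytest.fixture(scope="session")
def hinge_modes(hinge_pair):
    network = build_network(hinge_pair.open, rc=9.0)
    return network, compute_modes(build_hessian(network))


@pytest.fixture(scope="session")
def heavy_hinge():
    """Hinge toy with a 3x heavier static domain (lever asymmetry)."""
    pair = make_hinge_dimer(static_factor=3, seed=0)
    network = build_network(pair.open, rc=9.0)
    return pair, network, compute_modes(build_hessian(network))


@pytest.fixture(scope="session")
def dimer0():
    return make_symmetric_dimer_with_cochaperones(n_bound=0, seed=0)


@pytest.fixture(scope="session")
def dimer0_modes(dimer0):
    network = build_network(dimer0, rc=9.0)
    return network, compute_modes(build_hessian(network))


@pytest.fixture(scope="session")
def dimer2():
    return make_symmetric_dimer_with_cochaperones(n_bound=2, seed=0)


@pytest.fixture(scope="session")
def dimer2_modes(dimer2):
    network = build_network(dimer2, rc=9.0)
    return network, compute_modes(build_hessian(network))


@pytest.fixture(scope="session")
def dimer1_pair():
    return make_dimer_transition_pair(n_bound=1, seed=0)


def c2_permutation(n_protomer: int, n_cochaperone: int, n_bound: int):
    """Node permutation of the dimer fixture's two-fold symmetry."""
    perm = np.concatenate([np.arange(n_protomer, 2 * n_protomer),
                           np.arange(n_protomer)])
    if n_bound == 2:
        base = 2 * n_protomer
        perm = np.concatenate([
            perm,
            np.arange(base + n_cochaperone, base + 2 * n_cochaperone),
            np.arange(base, base + n_cochaperone)])
    return perm
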