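"""Anisotropic elastic network model and its normal modes.

Residue nodes within a cutoff distance Rc of each other are joined by
harmonic springs, all with the same spring constant gamma, giving the
potential

    H = 1/2 * sum_{i<j : d0_ij < Rc} gamma * (d_ij - d0_ij)**2

where d0_ij is the CA-CA distance in the reference structure and d_ij the
instantaneous one.  The Hessian of H at the reference structure is the
standard anisotropic network model matrix: each contact contributes the
3x3 block -gamma * e e^T (e the unit inter-node vector) off-diagonal, and
minus the row sum on the diagonal.  Unit masses are assumed throughout, so
the normal modes are the eigenpairs of the Hessian itself; a connected
network has exactly six zero modes (rigid translations and rotations).

The cutoff is calibrated by correlating mode-derived B-factors against the
experimental B-factor column of the input structure over a grid of Rc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

from .exceptions import ModeError, NetworkError
from .structures import StructureModel

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "build_network",
    "build_hessian",
    "compute_modes",
    "network_energy",
    "calc_bfactors",
    "calibrate_cutoff",
    "DEFAULT_CUTOFF",
    "DEFAULT_GAMMA",
]

DEFAULT_CUTOFF = 9.0   # Angstrom, chosen by B-factor correlation
DEFAULT_GAMMA = 1.0    # spring constant, arbitrary energy/A^2 units


@dataclass
class ElasticNetwork:
    """Contact topology and reference distances of one structure."""

    model: StructureModel
    rc: float
    gamma: float
    contacts: np.ndarray        # (n_contacts, 2) int, i < j
    reference_distances: np.ndarray  # (n_contacts,) float, 0 < d0 < rc

    @property
    def n_nodes(self) -> int:
        return self.model.n_nodes

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]

    def contact_table(self) -> pd.DataFrame:
        """Contacts as a 1-based (i, j, d0) table."""
        return pd.DataFrame({
            "i": self.contacts[:, 0] + 1,
            "j": self.contacts[:, 1] + 1,
            "d0": self.reference_distances,
        })

    def n_components(self) -> int:
        """Number of connected components of the contact graph."""
        n = self.n_nodes
        adj = coo_matrix(
            (np.ones(self.n_contacts),
             (self.contacts[:, 0], self.contacts[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def component_labels(self) -> np.ndarray:
        n = self.n_nodes
        adj = coo_matrix(
            (np.ones(self.n_contacts),
             (self.contacts[:, 0], self.contacts[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        return labels


@dataclass
class ModeSet:
    """Full eigensystem of the network Hessian.

    Mode numbering is 1-based over the ascending-sorted full spectrum,
    including the zero modes, so the first internal mode of a connected
    network is mode 7 (the convention used for reporting dominant modes).
    """

    eigenvalues: np.ndarray    # (3N,) ascending, >= 0 up to round-off
    eigenvectors: np.ndarray   # (3N, 3N), column M-1 is mode M, unit norm
    n_zero: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def nonzero_modes(self) -> np.ndarray:
        """1-based indices of the non-rigid-body modes."""
        return np.arange(self.n_zero + 1, self.n_modes + 1)

    def mode_vector(self, mode: int) -> np.ndarray:
        """Eigenvector of 1-based mode index, as an (N, 3) array."""
        if not 1 <= mode <= self.n_modes:
            raise ModeError(f"mode {mode} outside 1..{self.n_modes}")
        return self.eigenvectors[:, mode - 1].reshape(-1, 3)

    def mode_eigenvalue(self, mode: int) -> float:
        if not 1 <= mode <= self.n_modes:
            raise ModeError(f"mode {mode} outside 1..{self.n_modes}")
        return float(self.eigenvalues[mode - 1])


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(model: StructureModel, rc: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA) -> ElasticNetwork:
    """Connect all node pairs strictly closer than ``rc``.

    Coincident nodes (zero distance) are rejected: they would produce an
    undefined spring direction.
    """
    if model.n_nodes < 2:
        raise NetworkError("a network needs at least two nodes")
    if rc <= 0 or gamma <= 0:
        raise NetworkError("cutoff and spring constant must be positive")
    tree = cKDTree(model.coords)
    pairs = tree.query_pairs(rc, output_type="ndarray")  # strict d < rc
    if pairs.size:
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    d0 = np.linalg.norm(model.coords[pairs[:, 0]] - model.coords[pairs[:, 1]],
                        axis=1) if pairs.size else np.empty(0)
    if pairs.size and d0.min() <= 0.0:
        k = int(np.argmin(d0))
        raise NetworkError(
            f"coincident nodes {pairs[k, 0] + 1} and {pairs[k, 1] + 1}")
    # query_pairs uses d <= r at exact boundary floats; enforce strict d < rc
    keep = d0 < rc
    return ElasticNetwork(model=model, rc=float(rc), gamma=float(gamma),
                          contacts=pairs[keep],
                          reference_distances=d0[keep])


def build_hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N Hessian of the network potential at the reference."""
    n = network.n_nodes
    h = np.zeros((3 * n, 3 * n))
    coords = network.model.coords
    for (i, j), d0 in zip(network.contacts, network.reference_distances):
        e = (coords[j] - coords[i]) / d0
        block = network.gamma * np.outer(e, e)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] -= block
        h[sl_j, sl_i] -= block
        h[sl_i, sl_i] += block
        h[sl_j, sl_j] += block
    return h


def network_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Evaluate the harmonic potential at displaced coordinates."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[network.contacts[:, 0]]
                       - coords[network.contacts[:, 1]], axis=1)
    return float(0.5 * network.gamma
                 * np.sum((d - network.reference_distances) ** 2))


# ---------------------------------------------------------------------------
# normal modes
# ---------------------------------------------------------------------------

def compute_modes(hessian: np.ndarray, tol_zero: float = 1e-8) -> ModeSet:
    """Full eigendecomposition of a symmetric Hessian.

    Eigenvalues are sorted ascending; those below ``tol_zero`` times the
    largest eigenvalue are counted as zero (rigid-body) modes.  More than
    six zero modes indicates a disconnected network and is recorded as a
    warning on the returned :class:`ModeSet`.  Eigenvector signs are fixed
    deterministically (largest-magnitude component positive) so covariance
    signs are reproducible across runs and LAPACK builds.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ModeError("hessian must be square")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ModeError("hessian must be symmetric")
    vals, vecs = eigh(hessian)
    scale = max(vals[-1], 0.0)
    n_zero = int(np.sum(np.abs(vals) < tol_zero * max(scale, 1e-300)))
    # deterministic sign: largest-|component| entry made positive
    pivot = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[pivot, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    ms = ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero)
    if n_zero > 6:
        ms.warnings.append(
            f"{n_zero} zero modes (> 6): the network is disconnected")
    return ms


def calc_bfactors(modeset: ModeSet, network: ElasticNetwork | None = None,
                  ) -> np.ndarray:
    """Per-node mean-square fluctuation from the non-rigid modes.

    B_i is proportional to sum over nonzero modes of |q_i^M|^2 / lambda_M
    (the per-node trace of the Hessian pseudo-inverse); the arbitrary scale
    is fixed by normalizing to unit mean.
    """
    nz = modeset.nonzero_modes()
    if nz.size == 0:
        raise ModeError("no nonzero modes: cannot compute B-factors")
    q = modeset.eigenvectors[:, nz - 1].reshape(modeset.n_nodes, 3, -1)
    lam = modeset.eigenvalues[nz - 1]
    b = np.einsum("iam,iam,m->i", q, q, 1.0 / lam)
    return b / b.mean()


def calibrate_cutoff(model: StructureModel, rc_grid: list[float],
                     gamma: float = DEFAULT_GAMMA) -> pd.DataFrame:
    """Pearson correlation of computed vs experimental B-factors per cutoff.

    Returns one row per Rc with columns ``rc``, ``pearson_r``, ``n_zero``
    and ``disconnected``; the correlation uses only nodes carrying an
    experimental B-factor.  This reproduces the standard way of picking the
    contact cutoff for a CA network.
    """
    if model.bfactors is None:
        raise ModeError("structure carries no experimental B-factors")
    have_b = np.isfinite(model.bfactors)
    if have_b.sum() < 10:
        raise ModeError("need experimental B-factors on at least 10 nodes")
    b_exp = model.bfactors[have_b]
    if np.ptp(b_exp) == 0:
        raise ModeError("experimental B-factors are constant: "
                        "correlation undefined")
    rows = []
    for rc in rc_grid:
        network = build_network(model, rc=rc, gamma=gamma)
        modeset = compute_modes(build_hessian(network))
        if modeset.n_zero == modeset.n_modes:
            r = np.nan  # nothing but rigid pieces at this cutoff
        else:
            r, _ = pearsonr(calc_bfactors(modeset, network)[have_b], b_exp)
        rows.append({"rc": rc, "pearson_r": float(r),
                     "n_zero": modeset.n_zero,
                     "disconnected": modeset.n_zero > 6})
    return pd.DataFrame(rows)
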