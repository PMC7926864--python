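"""Structural perturbation method (SPM).

A point mutation at residue i is modeled as stiffening every spring
incident to i by a small amount dgamma.  The first-order shift of mode M's
eigenvalue under that perturbation is the quadratic form

    dw_i^M = q^M . dH_i . q^M
           = dgamma * sum_{j in contacts(i)} (e_ij . (q_j^M - q_i^M))**2

where dH_i is the network Hessian assembled over only the contacts of i
with spring constant dgamma, and e_ij the reference unit inter-node
vector.  The response is large exactly where the mode stretches or
compresses the local springs, so high-response residues trace the network
that transmits the conformational signal for that mode ("allostery wiring
diagram").  Rankings are independent of dgamma (the form is linear in it);
the top few percent of residues per mode are reported as hot spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import ElasticNetwork, ModeSet
from .exceptions import ConfigurationError, ModeError

__all__ = [
    "PerturbationResponse",
    "HotSpotSet",
    "spm_response",
    "select_hotspots",
    "coupling_report",
    "DEFAULT_DELTA_GAMMA",
    "DEFAULT_HOTSPOT_FRACTION",
]

DEFAULT_DELTA_GAMMA = 0.01      # perturbation as a fraction of gamma
DEFAULT_HOTSPOT_FRACTION = 0.02  # top 2% of responses per mode


@dataclass
class PerturbationResponse:
    """Per-node, per-mode eigenvalue responses dw_i^M (all >= 0)."""

    responses: np.ndarray   # (N, n_modes)
    modes: list[int]        # 1-based mode indices, column order
    delta_gamma: float      # perturbed spring constant, fraction of gamma

    @property
    def n_nodes(self) -> int:
        return self.responses.shape[0]

    def mode_column(self, mode: int) -> np.ndarray:
        if mode not in self.modes:
            raise ModeError(f"mode {mode} not in response set {self.modes}")
        return self.responses[:, self.modes.index(mode)]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses,
                            index=np.arange(1, self.n_nodes + 1),
                            columns=[f"mode_{m}" for m in self.modes])


@dataclass
class HotSpotSet:
    """Top-ranked SPM residues for one mode."""

    mode: int
    node_indices: np.ndarray  # 0-based, descending response
    responses: np.ndarray
    fraction: float | None
    count: int


def spm_response(network: ElasticNetwork, modeset: ModeSet,
                 modes=None,
                 delta_gamma: float = DEFAULT_DELTA_GAMMA,
                 ) -> PerturbationResponse:
    """Eigenvalue response of each mode to stiffening each node's springs.

    ``modes`` defaults to all nonzero modes.  ``delta_gamma`` is the
    perturbed spring constant as a fraction of the network's gamma; the
    response scales linearly with it, so rankings do not depend on it.
    """
    if delta_gamma <= 0:
        raise ModeError("delta_gamma must be positive")
    if modes is None:
        modes = [int(m) for m in modeset.nonzero_modes()]
    elif isinstance(modes, (int, np.integer)):
        modes = [int(modes)]
    else:
        modes = [int(m) for m in modes]
    if not modes:
        raise ModeError("empty mode subset")
    bad = [m for m in modes if m <= modeset.n_zero]
    if bad:
        raise ModeError(f"zero modes {bad} have no meaningful SPM response")

    n = network.n_nodes
    q = modeset.eigenvectors[:, [m - 1 for m in modes]].reshape(n, 3, -1)
    i, j = network.contacts[:, 0], network.contacts[:, 1]
    e = ((network.model.coords[j] - network.model.coords[i])
         / network.reference_distances[:, None])
    # per-contact, per-mode spring extension along the reference direction
    stretch = np.einsum("ca,cam->cm", e, q[j] - q[i])
    strain = delta_gamma * network.gamma * stretch ** 2
    responses = np.zeros((n, len(modes)))
    np.add.at(responses, i, strain)
    np.add.at(responses, j, strain)
    return PerturbationResponse(responses=responses, modes=modes,
                                delta_gamma=float(delta_gamma))


def select_hotspots(response: PerturbationResponse, mode: int,
                    fraction: float | None = DEFAULT_HOTSPOT_FRACTION,
                    count: int | None = None) -> HotSpotSet:
    """Top residues by SPM response for one mode.

    By default the top ``ceil(fraction * N)`` residues are kept (fraction
    selection); passing ``count`` instead fixes an absolute number.  Ties
    are broken by ascending node index, making the selection deterministic.
    """
    col = response.mode_column(mode)
    n = response.n_nodes
    if count is None:
        if fraction is None or not 0 < fraction <= 1:
            raise ModeError("fraction must be in (0, 1]")
        count = math.ceil(fraction * n)
    else:
        fraction = None
        if not 0 < count <= n:
            raise ModeError(f"count must be in 1..{n}")
    order = np.lexsort((np.arange(n), -col))  # descending, index tie-break
    top = order[:count]
    return HotSpotSet(mode=mode, node_indices=top, responses=col[top],
                      fraction=fraction, count=count)


def coupling_report(hotspot_sets: list[HotSpotSet],
                    segment_map: dict[str, tuple[int, int]],
                    n_nodes: int) -> pd.DataFrame:
    """Count hot-spot residues per named segment, per mode.

    Used to ask which chains of a complex carry the allosteric wiring
    (e.g. whether the hot spots of a mode sit mostly on the chaperone or
    mostly on the cochaperone).
    """
    seg_of = np.full(n_nodes, "", dtype=object)
    for name, (lo, hi) in segment_map.items():
        if lo < 1 or hi > n_nodes:
            raise ConfigurationError(
                f"segment {name!r} range ({lo}, {hi}) outside 1..{n_nodes}")
        seg_of[lo - 1:hi] = name
    rows = []
    for hs in hotspot_sets:
        counts = {name: 0 for name in segment_map}
        for idx in hs.node_indices:
            name = seg_of[idx]
            if name:
                counts[name] += 1
        for name in segment_map:
            rows.append({"mode": hs.mode, "segment": name,
                         "hotspots": counts[name]})
    return pd.DataFrame(rows)
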