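"""Mode-level observables: overlap, covariance, displacement.

Three quantities connect the normal modes to biology:

* **Overlap** I_M = |q^M . dr| / (|q^M| |dr|) measures how much of an
  observed conformational transition dr (e.g. open -> closed) a single
  mode M accounts for; I_M is in [0, 1] and the squares sum to 1 over the
  complete 3N-mode basis.  Modes with I_M at or above a threshold (default
  0.35) are called dominant.
* **Covariance** C_ij is the normalized cross-correlation of the motion of
  residues i and j within a mode or 1/lambda-weighted mode set: +1 means
  concerted motion, -1 opposed.
* **Displacement** dq_i^M = |q_i^M| is the per-residue amplitude within a
  normalized mode; profiles for a mode set are the plain sum of the
  per-mode profiles.

The overlap's absolute value is deliberate: the eigenvector sign is
arbitrary, and the bound 0 <= I_M <= 1 requires it.  The signed value is
retained internally for basis-completeness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import ModeSet
from .exceptions import ConfigurationError, ModeError, StructureError
from .structures import (
    NodeCorrespondence,
    StructureModel,
    positional_correspondence,
    superpose,
)

__all__ = [
    "TransitionVector",
    "OverlapProfile",
    "CovarianceMatrix",
    "transition_vector",
    "overlap",
    "covariance",
    "displacement",
    "segment_summary",
    "DEFAULT_OVERLAP_THRESHOLD",
]

DEFAULT_OVERLAP_THRESHOLD = 0.35


@dataclass
class TransitionVector:
    """Per-node displacement field between two corresponded conformations."""

    delta: np.ndarray          # (N, 3) Angstrom
    start_label: str
    end_label: str
    aligned: bool

    @property
    def n_nodes(self) -> int:
        return self.delta.shape[0]

    def flat(self) -> np.ndarray:
        return self.delta.reshape(-1)


@dataclass
class OverlapProfile:
    """Overlap of every mode with one transition, plus the dominant set."""

    values: np.ndarray         # (3N,) I_M, index M-1
    signed_values: np.ndarray  # pre-absolute-value inner products (internal)
    threshold: float
    n_zero: int

    @property
    def dominant_modes(self) -> list[int]:
        """Nonzero modes with I_M >= threshold, descending by overlap."""
        nz = np.arange(self.n_zero, len(self.values))
        hits = nz[self.values[nz] >= self.threshold]
        order = np.argsort(-self.values[hits], kind="stable")
        return [int(m) + 1 for m in hits[order]]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"mode": np.arange(1, len(self.values) + 1),
                             "overlap": self.values})


@dataclass
class CovarianceMatrix:
    """Normalized residue-residue cross-correlations for a mode set."""

    matrix: np.ndarray         # (N, N), NaN where undefined
    modes: list[int]           # 1-based modes included
    frequency_weighting: bool  # True: weights 1/sqrt(lambda); False: 1/lambda

    def table(self) -> pd.DataFrame:
        labels = np.arange(1, self.matrix.shape[0] + 1)
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# transition vector
# ---------------------------------------------------------------------------

def transition_vector(start: StructureModel, end: StructureModel,
                      correspondence: NodeCorrespondence | None = None,
                      align: bool = True) -> TransitionVector:
    """Displacement field from ``start`` to ``end`` over corresponded nodes.

    With ``align=True`` (default) the end conformation is first rigidly
    superposed onto the start over all corresponded nodes, so the field
    reflects internal deformation only; otherwise any rigid-body offset
    between the two frames leaks into the field.
    """
    if correspondence is None:
        correspondence = positional_correspondence(start, end)
    ia = correspondence.pairs[:, 0]
    ib = correspondence.pairs[:, 1]
    xs = start.coords[ia]
    xe = end.coords[ib]
    if align:
        sup = superpose(end.subset(ib), start.subset(ia))
        xe = xe @ sup.rotation.T + sup.translation
    return TransitionVector(delta=xe - xs, start_label=start.label,
                            end_label=end.label, aligned=align)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def overlap(modeset: ModeSet, tv: TransitionVector,
            threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> OverlapProfile:
    """Overlap I_M of every mode with the transition field."""
    d = tv.flat()
    if d.shape[0] != 3 * modeset.n_nodes:
        raise ModeError(
            f"transition has {d.shape[0]} components, modes have "
            f"{3 * modeset.n_nodes}")
    dnorm = np.linalg.norm(d)
    if dnorm < 1e-12:
        raise ModeError("zero-length transition: the two conformations "
                        "are identical")
    signed = (modeset.eigenvectors.T @ d) / dnorm  # eigenvectors unit norm
    return OverlapProfile(values=np.abs(signed), signed_values=signed,
                          threshold=threshold, n_zero=modeset.n_zero)


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def _resolve_modes(modeset: ModeSet, modes) -> list[int]:
    if isinstance(modes, str):
        if modes != "all-nonzero":
            raise ModeError(f"unknown mode selection {modes!r}")
        return [int(m) for m in modeset.nonzero_modes()]
    if isinstance(modes, (int, np.integer)):
        modes = [int(modes)]
    modes = [int(m) for m in modes]
    if not modes:
        raise ModeError("empty mode subset")
    for m in modes:
        if not 1 <= m <= modeset.n_modes:
            raise ModeError(f"mode {m} outside 1..{modeset.n_modes}")
    return modes


def covariance(modeset: ModeSet, modes="all-nonzero",
               frequency_weighting: bool = False,
               allow_zero_modes: bool = False) -> CovarianceMatrix:
    """Residue cross-correlation matrix over a mode subset.

    Each mode contributes q_i^M . q_j^M weighted by 1/lambda_M (or
    1/sqrt(lambda_M) with ``frequency_weighting``); the result is
    normalized per node pair so the diagonal is 1.  For a single mode the
    weight cancels.  Nodes that do not move in any requested mode give NaN
    rows/columns (undefined correlation).
    """
    mode_list = _resolve_modes(modeset, modes)
    zero = [m for m in mode_list if m <= modeset.n_zero]
    if zero and not allow_zero_modes:
        raise ModeError(f"zero modes {zero} in covariance subset; pass "
                        "allow_zero_modes=True to force")
    lam = np.array([modeset.mode_eigenvalue(m) for m in mode_list])
    if len(mode_list) == 1:
        w = np.ones(1)  # single mode: the weight cancels in normalization
    else:
        w = 1.0 / (np.sqrt(lam) if frequency_weighting else lam)
    q = np.stack([modeset.mode_vector(m) for m in mode_list], axis=2)
    g = np.einsum("iam,jam,m->ij", q, q, w)
    diag = np.diag(g).copy()
    dead = diag <= 0
    diag[dead] = np.nan
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(invalid="ignore"):
        c = g / denom
    return CovarianceMatrix(matrix=c, modes=mode_list,
                            frequency_weighting=frequency_weighting)


# ---------------------------------------------------------------------------
# displacement
# ---------------------------------------------------------------------------

def displacement(modeset: ModeSet, modes) -> np.ndarray:
    """Per-node amplitude profile dq_i for one mode or a mode-set sum.

    For one normalized mode the squared profile sums to 1; for a set, the
    per-mode profiles are summed arithmetically (the convention used when
    mapping the joint mobility of several dominant modes onto a structure).
    Requesting a zero mode is allowed but warned about, since rigid-body
    amplitudes carry no internal-motion information.
    """
    mode_list = _resolve_modes(modeset, modes)
    zero = [m for m in mode_list if m <= modeset.n_zero]
    if zero:
        warnings.warn(f"displacement over zero modes {zero}", stacklevel=2)
    profile = np.zeros(modeset.n_nodes)
    for m in mode_list:
        profile += np.linalg.norm(modeset.mode_vector(m), axis=1)
    return profile


# ---------------------------------------------------------------------------
# segment summaries
# ---------------------------------------------------------------------------

def segment_summary(data, segment_map: dict[str, tuple[int, int]],
                    ) -> pd.DataFrame:
    """Mean of a covariance matrix (per segment pair) or profile (per segment).

    Accepts a :class:`CovarianceMatrix`, a square array, or a 1-D profile.
    Segment ranges are 1-based inclusive and must lie inside the node index
    space of the data.
    """
    if isinstance(data, CovarianceMatrix):
        data = data.matrix
    arr = np.asarray(data, dtype=float)
    n = arr.shape[0]
    idx = {}
    for name, (lo, hi) in segment_map.items():
        if lo < 1 or hi > n:
            raise ConfigurationError(
                f"segment {name!r} range ({lo}, {hi}) outside 1..{n}")
        idx[name] = np.arange(lo - 1, hi)
    if arr.ndim == 1:
        rows = [{"segment": name, "mean": float(np.nanmean(arr[i]))}
                for name, i in idx.items()]
        return pd.DataFrame(rows)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise StructureError("expected a square matrix or 1-D profile")
    rows = []
    for name_a, ia in idx.items():
        for name_b, ib in idx.items():
            block = arr[np.ix_(ia, ib)]
            rows.append({"segment_a": name_a, "segment_b": name_b,
                         "mean": float(np.nanmean(block))})
    return pd.DataFrame(rows)
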