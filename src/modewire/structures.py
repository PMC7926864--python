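"""Coarse-grained structure handling.

A protein (or complex) is reduced to one node per residue, placed at the
alpha-carbon.  This module reads and writes such models in PDB format,
maintains node identity and named residue-range segments, superposes
conformations by least-squares (Kabsch), and assembles a symmetric 2:2
dimer-cochaperone complex from an asymmetric 2:1 one by overlaying the
bound protomer onto the free protomer and copying the cochaperone along.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

from .exceptions import (
    ConfigurationError,
    DegenerateSuperpositionError,
    StructureError,
)

__all__ = [
    "StructureModel",
    "NodeCorrespondence",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "positional_correspondence",
    "read_correspondence_tsv",
    "superpose",
    "apply_superposition",
    "assemble_symmetric_complex",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """One conformation of one assembly, as labeled CA nodes.

    Node identity is ``(chain_id, residue_number)``; node order is fixed and
    1-based in all external interfaces.  ``segment_map`` holds named,
    1-based, inclusive index ranges over the node list (e.g.
    ``{"protomerA": (1, 624)}``); an empty segment is ``(k, k - 1)``.
    """

    chain_ids: list[str]
    residue_numbers: np.ndarray
    residue_names: list[str]
    coords: np.ndarray
    bfactors: np.ndarray | None = None
    segment_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise StructureError("a structure needs at least one node")
        if len(self.chain_ids) != n or len(self.residue_numbers) != n \
                or len(self.residue_names) != n:
            raise StructureError("node attribute lengths disagree")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (n,):
                raise StructureError("bfactors must have one value per node")
        for name, (lo, hi) in self.segment_map.items():
            if hi < lo - 1 or lo < 1 or hi > n:
                raise StructureError(f"segment {name!r} range ({lo}, {hi}) "
                                     f"out of bounds for N={n}")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def segment_indices(self, name: str) -> np.ndarray:
        """0-based node indices of a named segment."""
        if name not in self.segment_map:
            raise ConfigurationError(f"unknown segment {name!r}")
        lo, hi = self.segment_map[name]
        return np.arange(lo - 1, hi)

    def subset(self, indices: np.ndarray, label: str = "") -> "StructureModel":
        """New model holding the given (0-based) nodes, without segments."""
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            chain_ids=[self.chain_ids[i] for i in idx],
            residue_numbers=self.residue_numbers[idx],
            residue_names=[self.residue_names[i] for i in idx],
            coords=self.coords[idx].copy(),
            bfactors=None if self.bfactors is None else self.bfactors[idx],
            label=label or self.label,
        )


@dataclass
class NodeCorrespondence:
    """Matched node pairs between two structures, as 0-based index pairs."""

    pairs: np.ndarray  # (M, 2) int: column 0 indexes A, column 1 indexes B
    complete: bool

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise StructureError("correspondence pairs must be (M, 2)")
        for side in (0, 1):
            col = self.pairs[:, side]
            if len(np.unique(col)) != len(col):
                raise StructureError("duplicate index in correspondence")

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_structure(pdb_text: str, chain_filter: set[str] | None = None,
                   label: str = "") -> StructureModel:
    """Parse PDB ATOM records into a CA-only :class:`StructureModel`.

    One node per residue, taken from its CA atom; HETATM records, waters and
    alternate locations beyond the first are ignored.  Experimental B-factors
    are retained (used by cutoff calibration).  Nodes are ordered by
    ``(chain_id, residue_number)``.

    Raises
    ------
    StructureError
        If no CA atom survives the chain filter, or a residue carries an
        insertion code (prepared models must not have any: node identity is
        ``(chain, residue number)`` alone).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", io.StringIO(pdb_text))
    records: list[tuple[str, int, str, np.ndarray, float]] = []
    for model in structure:
        for chain in model:
            if chain_filter is not None and chain.id not in chain_filter:
                continue
            for residue in chain:
                hetflag, resseq, icode = residue.id
                if hetflag.strip():
                    continue  # HETATM / water
                if "CA" not in residue:
                    continue
                if icode.strip():
                    raise StructureError(
                        f"insertion code {icode!r} at {chain.id}:{resseq}; "
                        "renumber the structure first")
                atom = residue["CA"]
                if atom.is_disordered():
                    warnings.warn(
                        f"multiple CA altlocs at {chain.id}:{resseq}; "
                        "keeping the first", stacklevel=2)
                    atom = sorted(atom.child_dict.values(),
                                  key=lambda a: a.get_altloc())[0]
                records.append((chain.id, resseq, residue.get_resname(),
                                atom.coord.astype(float), float(atom.bfactor)))
        break  # first MODEL only
    if not records:
        raise StructureError("no CA atoms found (after chain filtering)")
    records.sort(key=lambda r: (r[0], r[1]))
    return StructureModel(
        chain_ids=[r[0] for r in records],
        residue_numbers=np.array([r[1] for r in records]),
        residue_names=[r[2] for r in records],
        coords=np.array([r[3] for r in records]),
        bfactors=np.array([r[4] for r in records]),
        label=label,
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def write_structure(model: StructureModel,
                    per_node_scalar: np.ndarray | None = None) -> str:
    """Render CA-only ATOM records (fixed-column PDB, occupancy 1.00).

    If ``per_node_scalar`` is given it is linearly rescaled to [0, 99.99] and
    written into the B-factor column (rank order is preserved), which is how
    per-residue profiles are painted onto structures for molecular viewers.
    Otherwise stored B-factors (or 0.00) are written.
    """
    if per_node_scalar is not None:
        scalar = np.asarray(per_node_scalar, dtype=float)
        if scalar.shape != (model.n_nodes,):
            raise StructureError("per_node_scalar must have one value per node")
        lo, hi = scalar.min(), scalar.max()
        bcol = np.zeros_like(scalar) if hi == lo \
            else (scalar - lo) / (hi - lo) * 99.99
    elif model.bfactors is not None:
        bcol = np.clip(model.bfactors, 0.0, 999.99)
    else:
        bcol = np.zeros(model.n_nodes)

    lines = []
    serial = 0
    prev_chain = None
    for i in range(model.n_nodes):
        chain = model.chain_ids[i]
        if prev_chain is not None and chain != prev_chain:
            lines.append(f"TER   {serial + 1:>5d}      "
                         f"{model.residue_names[i - 1]:>3s} {prev_chain:1s}"
                         f"{model.residue_numbers[i - 1]:>4d}")
            serial += 1
        serial += 1
        x, y, z = model.coords[i]
        lines.append(
            f"ATOM  {serial:>5d}  CA  {model.residue_names[i]:>3s} "
            f"{chain:1s}{model.residue_numbers[i]:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bcol[i]:6.2f}"
            f"          {'C':>2s}")
        prev_chain = chain
    lines.append(f"TER   {serial + 1:>5d}      "
                 f"{model.residue_names[-1]:>3s} {prev_chain:1s}"
                 f"{model.residue_numbers[-1]:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------

def positional_correspondence(a: StructureModel,
                              b: StructureModel) -> NodeCorrespondence:
    """Match node i of A with node i of B (equal-length structures).

    This is the default for prepared conformation pairs, which guarantee the
    same node count and numbering; mismatched numbering needs an explicit
    mapping (see :func:`read_correspondence_tsv`).
    """
    if a.n_nodes != b.n_nodes:
        raise StructureError(
            f"positional correspondence needs equal node counts "
            f"({a.n_nodes} vs {b.n_nodes})")
    idx = np.arange(a.n_nodes)
    return NodeCorrespondence(pairs=np.column_stack([idx, idx]), complete=True)


def read_correspondence_tsv(text: str, n_a: int,
                            n_b: int) -> NodeCorrespondence:
    """Parse a two-column TSV of 1-based node indices (indexA, indexB)."""
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ia, ib = line.split("\t")[:2]
        pairs.append((int(ia) - 1, int(ib) - 1))
    arr = np.asarray(pairs, dtype=int)
    if arr.size and (arr.min() < 0 or arr[:, 0].max() >= n_a
                     or arr[:, 1].max() >= n_b):
        raise StructureError("correspondence index out of range")
    complete = len(pairs) == n_a == n_b
    return NodeCorrespondence(pairs=arr, complete=complete)


# ---------------------------------------------------------------------------
# superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose(mobile: StructureModel, target: StructureModel,
              correspondence: NodeCorrespondence | None = None,
              ) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation and translation minimizing the RMSD over the
    corresponded nodes (Kabsch, reflection-corrected).  With no
    correspondence given, equal-length structures are matched positionally.
    """
    if correspondence is None:
        correspondence = positional_correspondence(mobile, target)
    if len(correspondence) < 3:
        raise DegenerateSuperpositionError(
            "superposition needs at least 3 corresponded nodes")
    xm = mobile.coords[correspondence.pairs[:, 0]]
    xt = target.coords[correspondence.pairs[:, 1]]
    cm, ct = xm.mean(axis=0), xt.mean(axis=0)
    xm_c, xt_c = xm - cm, xt - ct
    # collinear (rank < 2) point sets leave the rotation underdetermined
    sv = np.linalg.svd(xm_c, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise DegenerateSuperpositionError("corresponded nodes are collinear")
    rot, _ = Rotation.align_vectors(xt_c, xm_c)
    rmat = rot.as_matrix()
    # residual-based rmsd: the solver's rssd loses precision to cancellation
    resid = xm_c @ rmat.T - xt_c
    rmsd = np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))
    return SuperpositionResult(rotation=rmat,
                               translation=ct - rmat @ cm,
                               rmsd=float(rmsd))


def apply_superposition(model: StructureModel,
                        result: SuperpositionResult) -> StructureModel:
    """Return a copy of ``model`` with the rigid transform applied."""
    new_coords = model.coords @ result.rotation.T + result.translation
    return replace(model, coords=new_coords)


# ---------------------------------------------------------------------------
# symmetric complex assembly
# ---------------------------------------------------------------------------

def assemble_symmetric_complex(
        asym: StructureModel,
        bound_segment: str = "protomer_bound",
        free_segment: str = "protomer_free",
        cochaperone_segment: str = "cochaperone") -> StructureModel:
    """Build the 2:2 symmetric complex from a 2:1 asymmetric one.

    The transform superposing the cochaperone-bound protomer onto the free
    protomer is computed and applied to a copy of the cochaperone, which is
    appended as a second cochaperone chain.  Input coordinates are preserved
    bit-for-bit; output node order is protomerA, protomerB, cochaperone1,
    cochaperone2, with the segment map renamed accordingly.
    """
    for name in (bound_segment, free_segment, cochaperone_segment):
        if name not in asym.segment_map:
            raise ConfigurationError(
                f"assembly needs segment {name!r}; have "
                f"{sorted(asym.segment_map)}")
    bound_idx = asym.segment_indices(bound_segment)
    free_idx = asym.segment_indices(free_segment)
    co_idx = asym.segment_indices(cochaperone_segment)
    if len(co_idx) == 0:
        return asym
    if len(bound_idx) != len(free_idx):
        raise ConfigurationError(
            "bound and free protomers must correspond bijectively "
            f"({len(bound_idx)} vs {len(free_idx)} nodes)")

    bound = asym.subset(bound_idx)
    free = asym.subset(free_idx)
    sup = superpose(bound, free)
    co = asym.subset(co_idx)
    co2 = apply_superposition(co, sup)

    used = set(asym.chain_ids)
    new_chain = next(c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if c not in used)
    n_in, n_co = asym.n_nodes, len(co_idx)
    return StructureModel(
        chain_ids=asym.chain_ids + [new_chain] * n_co,
        residue_numbers=np.concatenate([asym.residue_numbers,
                                        co2.residue_numbers]),
        residue_names=asym.residue_names + list(co2.residue_names),
        coords=np.vstack([asym.coords, co2.coords]),
        bfactors=None,
        segment_map={
            "protomerA": asym.segment_map[bound_segment],
            "protomerB": asym.segment_map[free_segment],
            "cochaperone1": asym.segment_map[cochaperone_segment],
            "cochaperone2": (n_in + 1, n_in + n_co),
        },
        label=(asym.label + "+sym" if asym.label else "symmetric complex"),
    )
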