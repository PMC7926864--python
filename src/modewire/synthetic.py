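"""Synthetic structure fixtures with known ground-truth dynamics.

Real chaperone systems are large and their prepared structures require
external modeling, so every pipeline stage is exercised here on small
generated structures whose correct answer is known by construction:

* a near-linear bead chain (basic network/spectrum checks);
* a two-domain hinge pair: compact domains joined at a two-node hinge,
  whose "closed" conformation is the "open" one with one domain rigidly
  rotated about the hinge axis — a toy for an open -> closed transition
  with a known displacement field, whose softest internal mode is the
  hinge motion;
* a C2-symmetric homodimer with 0, 1 or 2 cochaperone clusters docked on
  the protomer flanks, emulating an 0/1/2-bound chaperone-cochaperone
  series; the 2-bound model is produced by the same symmetric-assembly
  overlay used for real complexes.

Domains are jittered FCC-packed clusters, not folds: only contact
topology matters for elastic-network behavior.  All generators are
deterministic given their seed, and ground-truth displacement fields are
kept in memory / JSON at full precision (PDB files round coordinates to
3 decimals).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import StructureModel, assemble_symmetric_complex, \
    write_structure

__all__ = [
    "ToyPair",
    "make_chain",
    "make_hinge_dimer",
    "make_symmetric_dimer_with_cochaperones",
    "make_dimer_transition_pair",
    "write_fixture_set",
]

CA_SPACING = 3.8  # typical consecutive CA-CA distance, Angstrom


@dataclass
class ToyPair:
    """Two conformations related by a known displacement field."""

    open: StructureModel
    closed: StructureModel
    true_delta: np.ndarray  # (N, 3); closed = open + true_delta exactly
    description: str
    seed: int


def _model(coords: np.ndarray, chains: list[str],
           segment_map: dict[str, tuple[int, int]] | None = None,
           label: str = "") -> StructureModel:
    resnums = []
    prev = None
    k = 0
    for c in chains:
        k = k + 1 if c == prev else 1
        resnums.append(k)
        prev = c
    return StructureModel(
        chain_ids=list(chains),
        residue_numbers=np.array(resnums),
        residue_names=["ALA"] * len(chains),
        coords=coords,
        segment_map=segment_map or {},
        label=label,
    )


def _fcc_cluster(n: int, rng: np.random.Generator,
                 nn_dist: float = CA_SPACING, jitter: float = 0.35,
                 ) -> np.ndarray:
    """Compact cluster of n points on a jittered FCC lattice, centered."""
    a = nn_dist * math.sqrt(2.0)  # FCC lattice constant for given nn dist
    m = max(2, math.ceil((2 * n) ** (1 / 3)))
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                if (i + j + k) % 2 == 0:  # FCC as even sites of simple cubic
                    pts.append((i, j, k))
    pts = np.array(pts, dtype=float) * (a / 2.0)
    pts = pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")][:n]
    pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return pts - pts.mean(axis=0)


def make_chain(n: int, spacing: float = CA_SPACING, jitter: float = 0.0,
               seed: int = 0) -> StructureModel:
    """Near-linear bead chain along x, reproducible from the seed."""
    if n < 2:
        raise ValueError("chain needs at least 2 nodes")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    if jitter > 0:
        # per-node sigma jitter/sqrt(2), so consecutive distances deviate
        # with standard deviation ~jitter
        coords += rng.normal(scale=jitter / np.sqrt(2.0), size=coords.shape)
    return _model(coords, ["A"] * n, {"chain": (1, n)},
                  label=f"chain n={n} seed={seed}")


def _rot_z(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_hinge_dimer(n_per_domain: int = 30,
                     hinge_angle_open: float = 0.0,
                     hinge_angle_closed: float = 15.0,
                     seed: int = 0,
                     static_factor: int = 1,
                     fringe_gap: float = 2.5,
                     hinge_half_gap: float = 1.9) -> ToyPair:
    """Two compact domains joined at a two-node hinge on the z-axis.

    The static domain sits on the -x side (``static_factor`` times more
    nodes than the moving one), the moving domain on the +x side rotated
    in-plane by ``hinge_angle_open`` degrees; the closed conformation
    rotates the moving domain rigidly about the z-axis to
    ``hinge_angle_closed``.  Each domain's inner fringe sits
    ``fringe_gap`` Angstrom from the hinge axis, so the fringes share a
    few contacts near the axis: the in-plane rotation is then softly
    restrained (no spurious zero mode) while remaining the softest
    internal motion.  A ``static_factor`` > 1 concentrates the soft-mode
    amplitude on the light moving domain, the analogue of a small domain
    swinging against a large anchored one.  Node order: static domain,
    hinge pair, moving domain; ``true_delta`` is exactly zero off the
    moving domain.
    """
    rng = np.random.default_rng(seed)
    n_static = static_factor * n_per_domain
    cs = _fcc_cluster(n_static, rng)
    cm = _fcc_cluster(n_per_domain, rng)
    if static_factor == 1:
        # symmetric arms: center placement keeps the fringe contact count
        # in the narrow band where the in-plane rotation is the softest mode
        offset = 9.0
        static = cs + np.array([-offset, 0.0, 0.0])
        moving0 = cm + np.array([offset, 0.0, 0.0])
    else:
        # a bigger static cluster is placed by its fringe, not its center,
        # so the hinge region geometry stays comparable
        static = cs + np.array([-(fringe_gap + cs[:, 0].max()), 0.0, 0.0])
        moving0 = cm + np.array([fringe_gap - cm[:, 0].min(), 0.0, 0.0])
    moving_open = moving0 @ _rot_z(hinge_angle_open).T
    moving_closed = moving0 @ _rot_z(hinge_angle_closed).T
    hinge = np.array([[0.0, 0.0, -hinge_half_gap],
                      [0.0, 0.0, hinge_half_gap]])
    chains = ["A"] * n_static + ["A"] * 2 + ["B"] * n_per_domain
    segs = {"static": (1, n_static),
            "hinge": (n_static + 1, n_static + 2),
            "moving": (n_static + 3, n_static + 2 + n_per_domain)}
    open_coords = np.vstack([static, hinge, moving_open])
    closed_coords = np.vstack([static, hinge, moving_closed])
    return ToyPair(
        open=_model(open_coords, chains, segs,
                    label=f"hinge open seed={seed}"),
        closed=_model(closed_coords, chains, segs,
                      label=f"hinge closed seed={seed}"),
        true_delta=closed_coords - open_coords,
        description=(f"hinge dimer: {n_static}+{n_per_domain} nodes, "
                     f"{hinge_angle_open}->{hinge_angle_closed} deg"),
        seed=seed,
    )


def make_symmetric_dimer_with_cochaperones(
        n_protomer: int = 40, n_cochaperone: int = 20,
        n_bound: int = 0, seed: int = 0) -> StructureModel:
    """C2-symmetric homodimer with 0, 1 or 2 docked cochaperone clusters.

    Protomer B is the exact image of protomer A under a 180-degree
    rotation about z, so the unliganded dimer is exactly two-fold
    symmetric and symmetry-breaking by a single bound cochaperone is
    attributable to the cochaperone alone.  Cochaperone 1 is docked on
    the outer flank of protomer A with a contact-rich interface (>= 5
    inter-chain contacts at the standard 9 A cutoff); the 2-bound model
    is generated from the 1-bound model via
    :func:`~modewire.structures.assemble_symmetric_complex`, exactly as a
    symmetric complex is built from a real asymmetric one.
    """
    if n_protomer < 4 or n_cochaperone < 4:
        raise ValueError("protomer and cochaperone need >= 4 nodes each")
    if n_bound not in (0, 1, 2):
        raise ValueError("n_bound must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    prot = _fcc_cluster(n_protomer, rng)
    # dock the dimer: shift A so its inner fringe sits 2 A off the C2 axis
    prot_a = prot + np.array([2.0 - prot[:, 0].min(), 0.0, 0.0])
    prot_b = prot_a * np.array([-1.0, -1.0, 1.0])  # exact C2 about z
    np_, nc = n_protomer, n_cochaperone
    if n_bound == 0:
        coords = np.vstack([prot_a, prot_b])
        return _model(coords, ["A"] * np_ + ["B"] * np_,
                      {"protomerA": (1, np_),
                       "protomerB": (np_ + 1, 2 * np_)},
                      label=f"dimer 0-bound seed={seed}")
    co = _fcc_cluster(n_cochaperone, rng)
    co1 = co + np.array([prot_a[:, 0].max() + 3.5 - co[:, 0].min(), 0.0, 0.0])
    coords = np.vstack([prot_a, prot_b, co1])
    asym = _model(
        coords, ["A"] * np_ + ["B"] * np_ + ["C"] * nc,
        {"protomer_bound": (1, np_),
         "protomer_free": (np_ + 1, 2 * np_),
         "cochaperone": (2 * np_ + 1, 2 * np_ + nc)},
        label=f"dimer 1-bound seed={seed}")
    if n_bound == 1:
        return asym
    return assemble_symmetric_complex(asym)


def make_dimer_transition_pair(
        n_protomer: int = 40, n_cochaperone: int = 20,
        n_bound: int = 1, closing_angle: float = 12.0,
        seed: int = 0) -> ToyPair:
    """Dimer fixture plus a scissor-closed companion conformation.

    The closed state rotates each protomer about the dimer's two-fold
    (z) axis toward the other by ``closing_angle`` degrees, while any
    bound cochaperone stays where it was — mirroring the situation where
    the reference transition is known for the chaperone dimer alone and
    the cochaperone has no counterpart in the end state.  ``true_delta``
    is therefore exactly zero on cochaperone nodes.
    """
    start = make_symmetric_dimer_with_cochaperones(
        n_protomer, n_cochaperone, n_bound, seed)
    c2 = start.coords.copy()
    c2[:n_protomer] = start.coords[:n_protomer] @ _rot_z(closing_angle).T
    c2[n_protomer:2 * n_protomer] = (
        start.coords[n_protomer:2 * n_protomer] @ _rot_z(-closing_angle).T)
    end = StructureModel(
        chain_ids=list(start.chain_ids),
        residue_numbers=start.residue_numbers.copy(),
        residue_names=list(start.residue_names),
        coords=c2,
        segment_map=dict(start.segment_map),
        label=start.label + " closed")
    return ToyPair(
        open=start, closed=end, true_delta=c2 - start.coords,
        description=(f"dimer {n_bound}-bound scissor closure "
                     f"{closing_angle} deg"),
        seed=seed)


def write_fixture_set(outdir: str | Path, seed: int = 0) -> dict:
    """Write the standard fixture suite as PDB files plus a JSON manifest.

    The manifest records every file with its seed and node count;
    ground-truth displacement fields are stored in a separate JSON file at
    full precision (PDB coordinates are rounded to 3 decimals).
    Re-running with the same seed reproduces the files byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []

    def _write(name: str, model: StructureModel, used_seed: int,
               ground_truth_ref: str | None = None) -> None:
        path = outdir / name
        path.write_text(write_structure(model))
        entries.append({"file": name, "seed": used_seed,
                        "n_nodes": model.n_nodes,
                        "ground_truth_ref": ground_truth_ref})

    _write("chain.pdb", make_chain(50, jitter=0.3, seed=seed), seed)
    pair = make_hinge_dimer(seed=seed)
    gt = {"true_delta": pair.true_delta.tolist(),
          "description": pair.description, "seed": seed}
    (outdir / "hinge_ground_truth.json").write_text(
        json.dumps(gt, indent=1, sort_keys=True))
    _write("hinge_open.pdb", pair.open, seed, "hinge_ground_truth.json")
    _write("hinge_closed.pdb", pair.closed, seed, "hinge_ground_truth.json")
    for nb in (0, 1, 2):
        _write(f"dimer_{nb}bound.pdb",
               make_symmetric_dimer_with_cochaperones(n_bound=nb, seed=seed),
               seed)
    manifest = {"seed": seed, "files": entries}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
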