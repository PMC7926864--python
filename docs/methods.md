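# Methods

## Model

Proteins and complexes are reduced to one node per residue at the Cα
position. Nodes strictly closer than a cutoff `Rc` are connected by
harmonic springs with one global spring constant `γ`:

    H = ½ Σ_{i<j : d⁰_ij < Rc} γ (d_ij − d⁰_ij)²

The Hessian at the reference structure is the standard anisotropic
network matrix: off-diagonal 3×3 blocks `−γ ê_ij ê_ijᵀ` per contact
(`ê_ij` the reference unit separation), diagonal blocks minus the row
sums. Masses are uniform and set to 1 — the coarse-grained model carries
no mass information, and uniform masses are the standard Cα-network
convention — so normal modes are the eigenpairs of the Hessian itself.
Mode numbering is 1-based over the ascending full spectrum *including*
the six rigid-body zero modes; the first internal mode of a connected
assembly is therefore "mode 7", matching the convention used when
dominant modes of chaperone models are quoted.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `Rc` | 9.0 | Å | contact cutoff; calibrated by Pearson correlation of computed vs experimental B-factors over a grid |
| `γ` | 1.0 | energy/Ų (arbitrary) | global spring constant; rescaling scales all eigenvalues and leaves eigenvectors, covariance and SPM rankings unchanged |
| `overlap_threshold` | 0.35 | – | dominance cutoff on `I_M` |
| `hotspot_fraction` | 0.02 | – | top fraction of SPM responses kept per mode; `count = ceil(fraction·N)` (38 for N = 1853); an absolute `count` is accepted as an alternative because the quoted "38 per model" is ambiguous between a fixed count and a fixed fraction across models of different size |
| `delta_gamma` | 0.01 | fraction of γ | SPM perturbation magnitude; responses are linear in it, so only comparisons against rediagonalization are sensitive, and a small value keeps first-order perturbation theory accurate |
| `tol_zero` | 1e-8 | relative | eigenvalues below `tol_zero · λ_max` count as zero modes |

## Numerical choices

* **Eigensolver.** Dense symmetric `scipy.linalg.eigh` on the full
  3N×3N Hessian (N ≲ 3000 in practice; the 2458-node complex is a
  ~7400-dimension problem, about a minute on one CPU). Eigenvector signs
  are fixed deterministically by making each vector's largest-magnitude
  component positive, so covariance signs and CSV outputs reproduce
  exactly across runs and LAPACK builds.
* **Contacts.** Strict inequality `d < Rc` (boundary ties are
  measure-zero but documented); coincident nodes are an error because
  the spring direction is undefined. kd-tree pair search, verified in
  tests against the O(N²) all-pairs oracle.
* **Overlap.** The numerator carries an absolute value: the eigenvector
  sign is arbitrary and the bound `0 ≤ I_M ≤ 1` requires it. The signed
  inner products are retained internally (basis-completeness checks use
  them). The denominator is the product of Euclidean norms.
* **Transition field.** The end conformation is rigid-body superposed
  onto the start over all corresponded nodes before subtraction
  (`align=True` default). Without this, rigid offsets between the two
  frames leak into Δr and inflate zero-mode overlap; with it, `I_M`
  reflects internal deformation only. This is an assumption when
  comparing to published overlap values, which do not state whether the
  conformations were pre-superposed.
* **Covariance weighting.** The per-mode weight is `1/λ_M` (thermal
  covariance convention). Whether published formulas intend the
  eigenvalue or the frequency `√λ` is ambiguous; a
  `frequency_weighting` switch exposes the alternative, and single-mode
  matrices — the ones shown per dominant mode — are identical under
  either choice because the weight cancels in the normalization.
* **Superposition.** Kabsch via `scipy` `Rotation.align_vectors`
  (reflection-corrected, det = +1 always); fewer than three pairs or a
  collinear set raises a degenerate-superposition error. RMSD is
  recomputed from residuals rather than taken from the solver, which
  loses precision to cancellation near zero.
* **SPM evaluation.** A mutation at residue i perturbs *all* springs
  incident to i (the literal index set of the perturbation sum). The
  response is evaluated as the quadratic form `q^M·δH_i·q^M`, the exact
  first-order eigenvalue shift; tests require agreement with full
  rediagonalization within 1 % at `δγ = 1e-4 γ` for every node of a
  30-node toy. Hot-spot ties are broken by ascending node index.
* **Node identity.** `(chain, residue number)`; insertion codes are
  rejected (prepared models have none), HETATM records, waters and
  altlocs beyond the first are ignored on read. PDB output is
  fixed-column, CA-only, occupancy 1.00; per-node scalars written to the
  B-factor column are linearly rescaled to [0, 99.99].

## Symmetric-complex assembly

The 2:2 complex is built from the 2:1 complex exactly as described for
the real system: the cochaperone-bound protomer is superposed onto the
free protomer (all corresponded residues are used in the fit — which
subset the original procedure used is not stated, and all-residue is the
natural default), and the resulting transform is applied to a copy of
the cochaperone. Input coordinates are preserved bit-for-bit; at the
published chain sizes (624 + 624 + 605) the output has 2458 nodes with
the second cochaperone occupying positions 1854–2458.

## Synthetic fixtures: what they emulate, and what they do not

Domains are jittered FCC-packed clusters — only contact topology matters
for elastic-network behaviour, so no attempt is made at realistic fold
geometry, sequence (poly-alanine labels), or side-chain packing. All
generators are deterministic given their seed; ground-truth displacement
fields are kept at full precision in JSON because PDB rounds to 3
decimals.

* **Hinge pair.** Two clusters on the ±x axis joined by a two-node
  hinge on the z axis; the closed form rotates the moving cluster
  rigidly about z. Geometry matters here: if the moving cluster touched
  *only* the two hinge nodes, rotation about the axis through them
  would cost no energy at all (a spurious seventh zero mode — any
  rotation about a line through two anchor points preserves the
  distances to both). The clusters are therefore placed (centers ±9 Å)
  so their inner fringes share a handful of contacts near the axis,
  which softly restrain the rotation while keeping it the softest
  internal motion; with this placement the lowest internal mode carries
  ≥ 0.93 of the constructed transition across seeds. A
  `static_factor > 1` variant makes the static cluster proportionally
  heavier (placed by its fringe so the hinge region is unchanged),
  concentrating soft-mode amplitude on the light moving domain — that
  variant exhibits the textbook covariance signature (intra-domain
  blocks positive, inter-domain block negative) and a > 3× moving/static
  amplitude ratio, which the symmetric toy does not: with equal arms
  the momentum-compensating translation in each mode shifts the
  effective rotation axes into the domains and scrambles the block
  means.
* **Dimer series.** Protomer B is the exact image of protomer A under a
  180° rotation about z (C2), so the unliganded dimer is exactly
  two-fold symmetric and any asymmetry after docking one cochaperone is
  attributable to the cochaperone. C2 rather than a literal mirror is
  deliberate: the assembly overlay enforces a proper rotation, and a
  reflection-related pair cannot be superposed by one — real homodimers
  are C2 for the same reason. The cochaperone cluster is docked on the
  outer flank of protomer A with ≥ 5 interface contacts at Rc = 9 Å;
  the 2-bound model is generated through `assemble_symmetric_complex`
  itself, exercising the same code path used for real complexes.
* **Dimer transition pair.** The "closed" companion rotates each
  protomer 12° about the C2 axis toward the other (a scissor closure)
  while any bound cochaperone stays put — mirroring analyses where the
  reference transition is known for the chaperone dimer alone and the
  cochaperone has no counterpart in the end state. On this fixture the
  dominant modes show lower mean displacement on the bound protomer
  than the free one, the qualitative suppression seen in the real
  asymmetric complex. The effect is a tendency, not a certainty, of a
  random 100-node geometry: occasional seeds yield dominant sets mixed
  with cochaperone-swing modes where the inequality reverses, which is
  why the acceptance script reports the ratio averaged over replicate
  geometries.

Passing tests on these fixtures demonstrate that the machinery — network
construction, spectra, overlap bookkeeping, SPM algebra, assembly —
is correct, and that the qualitative symmetry/asymmetry phenomenology is
reproduced at toy scale. They do not demonstrate agreement with the
published dominant-mode overlaps of the real chaperone models, which
depend on externally prepared full-length structures (homology-completed
and docked); `run_published_reproduction` accepts such structures and
tabulates computed vs published values (±0.15 tolerance annotation, node
counts gated at 1248/1853/2458) but cannot run without them.

## Problem sizes

Default test and acceptance runs use 30–120-node toys (62-node hinge,
80/100/120-node dimer series) — large enough for well-separated spectra
and at least five clean internal modes, small enough that the full suite
runs in seconds. The assembly-count checks run at the real chain sizes
(1853/2458 nodes) but involve no eigendecomposition.

## Known limitations

* Distance-weighted or sequence-specific spring constants, Gaussian
  (isotropic scalar) network variants, and sparse partial eigensolvers
  are out of scope.
* B-factor calibration compares shapes (Pearson r), not absolute scales;
  computed B-factors are returned normalized to unit mean.
* `calibrate_cutoff` reports NaN for cutoffs so small the network has no
  internal modes at all, and flags any cutoff that disconnects the
  structure.
* Overlap requires matched node counts between the two conformations;
  partial correspondences are supported (unmatched nodes contribute zero
  displacement) but conclusions then depend on the matched subset.
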