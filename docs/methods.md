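# Methods

This note records the models implemented in `cspkit`, the defaults and
why they were chosen, what the synthetic data do and do not emulate,
and the known limitations. It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## Scope and philosophy

`cspkit` is a desk-scale implementation of structure solution by
crystal structure prediction: everything runs on one CPU in minutes,
so simulation sizes are deliberately small (tens of search candidates,
8–12-molecule comparison clusters, toy molecules for the expensive
end-to-end exercises). The method code paths are identical at any
scale; only the budgets are small. All randomness flows from explicit
integer seeds, and every search result carries enough provenance
(seed, index, generation, parents) to be regenerated exactly.

## Crystallographic core

* Cartesianization puts **a** along x and **b** in the x–y plane; the
  cell matrix holds lattice vectors as columns. Fractional coordinates
  wrap to [0, 1) by molecular centroid, so rigid molecules are never
  split across images.
* Space-group operations come from gemmi's symmetry tables, restricted
  to the 14 groups the search supports (the 13 most common for organic
  molecules plus P2₁2₁2), standard settings only. gemmi is the
  field-standard library and its tables are exhaustively validated;
  the test suite still asserts closure, identity and multiplicity for
  every group in scope. Seven of the groups contain improper
  operations; these invert the molecule, which is accepted silently
  because the molecules in scope (planar coumarin, the toy bodies) are
  achiral or handled by the inversion-aware comparison code.
* Orientations are unit quaternions with the double cover removed by
  forcing a nonnegative scalar part.
* Niggli reduction delegates to gemmi's Gruber-vector implementation
  and returns the change-of-basis matrix.
* CIF I/O (gemmi.cif underneath) writes the asymmetric unit with
  symmetry operator strings and per-molecule site labels, so reading
  recovers molecule blocks, not just a bag of atoms.

## Force field and lattice energy

* Intermolecular-only 12-6 Lennard-Jones plus point charges.
  Combining rules are geometric mean for both ε and σ (the OPLS
  family's convention, matching the kind of force field this pipeline
  is normally run with). Parameters live in small per-class tables;
  the bundled coumarin typing distinguishes aromatic C/H, the carbonyl
  C and O, and the ring (ester-like) O.
* The bundled coumarin charges are a synthetic stand-in: Gasteiger
  PEOE (electronegativity-equalization) values computed once for the
  2H-chromen-2-one connectivity and frozen into the source. They are
  chemically sensible but not fitted to any electronic-structure
  density, so absolute coumarin energies from this model are
  illustrative; no quantitative claim in the tests depends on them.
* Ewald summation: real-space erfc sum with cutoff 12 Å and damping
  α = 0.3 Å⁻¹ by default; reciprocal-space cutoff auto-tuned from a
  continuum tail estimate (err ≈ k_e Σq² α/√π · erfc(k_c/2α)) to an
  accuracy target of 10⁻⁵ kJ/mol per cell, because a fixed literal
  cutoff cannot converge arbitrary cells; a literal reciprocal cutoff
  remains selectable. Rigid-intramolecular pairs are excluded from the
  real part and corrected out of the reciprocal part; the correction
  is constant for rigid bodies.
* **Energy-shifted truncation.** Both real-space kernels are shifted
  so the pair energy vanishes at the cutoff. Plain truncation leaves
  O(10⁻³ kJ/mol) discontinuities as pairs cross the cutoff during
  optimization, which stalls quasi-Newton line searches; with the
  shift, the perturbed-minimum recovery test converges to machine
  precision. At converged cutoffs the shift is below 10⁻⁹ of the
  Madelung and fcc-LJ reference values.
* Optimization: L-BFGS-B over the asymmetric-unit DOFs only (symmetry
  is enforced by construction — images follow their parent), with
  analytic gradients for placements. Rotations are parametrized as
  rotation-vector increments applied multiplicatively to the current
  quaternion; the SO(3) left Jacobian maps world-frame torques to
  parameter gradients so the analytic gradient is exact at finite
  increments. Free cell parameters (those the crystal system leaves
  free) use central finite differences. Default tolerances: gradient
  1e-4 kJ/mol per Å (or rad), 500 iterations, restarts re-center the
  rotation parametrization. Non-convergence flags the candidate
  instead of raising.

## Packing search

* Centroids are sampled uniformly in the full fractional cube rather
  than in exact per-group asymmetric units; the duplicates this
  creates are removed downstream, which is simpler and correct.
* Free cells draw a target density uniformly from the density window
  (default 0.8–1.6 g/cm³, bracketing the ~1.24–1.40 g/cm³ range of
  the coumarin family), a log-normal shape, and the free angles from
  75–115°; the cell is then scaled to the drawn density.
* The feasibility filter rejects candidates with any intermolecular
  contact below 0.65 × (sum of vdW radii) (gemmi's radii). The factor
  is a common packing heuristic and is configurable; generation fails
  with diagnostics after a bounded number of attempts.
* The evolutionary layer uses 50% heredity (cell from one parent,
  placements from another, same group), 30% placement/lattice
  mutation, 20% fresh random, elitism 1. These fractions are this
  package's defaults for a small-population search, not values taken
  from any reference implementation.

## Duplicate removal and structure identity

* RDF fingerprints: intermolecular interatomic distances to 7 Å per
  element pair, Gaussian-smeared with width 0.25 Å, normalized per
  molecule (supercell invariant). Distance is L2 between
  unit-normalized fingerprint vectors; candidates below 0.05 proceed
  to confirmation. The 0.05 threshold was calibrated on synthetic
  jittered copies.
* Cluster RMSD: n-molecule clusters (default 20; tests use 8–12 for
  speed on the same code path) around each choice of central molecule,
  correspondence by greedy centroid assignment refined against the
  growing superposition, initial rotations from the central-molecule
  Kabsch fit plus frames built from a chemically defined molecular
  axis and near-neighbor directions (these resolve the rotation left
  free by near-linear or symmetric central molecules). The second
  cluster carries a 0.5 Å radius margin so ties at the cluster
  boundary cannot exclude a legitimate partner. Final superposition
  is Kabsch on heavy atoms with element-restricted optimal atom
  assignment inside each matched molecule (so molecules with internal
  symmetry compare correctly). Inversion (enantiomorph) matching is
  allowed by default. Identity bar: RMSD < 0.3 Å.

## Powder diffraction

* Kinematic intensities: IT92 form factors (gemmi tables), isotropic
  displacement B = 3 Å² by default (room-temperature organic),
  multiplicities from the Laue class, systematic absences from the
  group's operators, LP = (1 + cos²2θ)/(sin²θ cosθ).
* Pseudo-Voigt profiles with Caglioti FWHM² = U tan²θ + V tanθ + W and
  η linear in 2θ; a single refinable 2θ zero shift; Chebyshev
  background (default order 6) standing in for the amorphous halo of
  resin-stabilized samples.
* Similarity is a de Gelder-style weighted cross-correlation with a
  0.5° triangular window, after mean-centering; candidate matching
  additionally subtracts an iteratively clipped Chebyshev baseline
  from the observation first — without this the broad halo dominates
  the correlation and ranking fails. Pattern matching in this package
  is quantitative by design (a score in [0, 1]), replacing visual
  comparison.
* Lattice refinement: strict indexing (exactly one symmetry-unique
  reflection per observed peak within the window, ambiguities raise
  with the colliding hkl) preceded by a coarse isotropic scale prefit
  of the starting cell over ±8%, which is what lets a starting cell a
  few percent off still index. Standard errors come from the
  least-squares covariance.
* Rigid-body refinement minimizes Σw(I_obs − I_calc)² with
  w = 1/max(I_obs, 1) (Poisson counting weights); molecules move only
  as rigid bodies; scale and zero shift always refine, placements /
  cell / profile / background by request. R_p, R_wp, R_exp use the
  standard definitions with N − P degrees of freedom, and
  χ² = (R_wp/R_exp)² holds identically. Single phase only; profile
  asymmetry, preferred orientation and multi-phase mixtures are out of
  scope.

## Thermodynamics

* Melting-point relation: ΔG = (T_m(ref) − T_m)·ΔH_fus/T_m(ref) with
  temperatures converted to kelvin via 273.15. The kelvin convention
  is load-bearing: it is what reproduces the published penalty values
  for the coumarin family.
* Phonons are computed over **rigid-body** (translational +
  librational) DOFs, not atomic ones: the force field is
  intermolecular-only, so intramolecular modes are undefined in this
  model and the rigid-body treatment is the consistent harmonic
  description. This is a deliberate deviation from all-atom treatments
  and means intramolecular vibrational contributions to polymorph free
  energy differences are absent.
* Hessians are central finite differences (10⁻³ Å / rad) of the
  analytic gradient on a supercell with every perpendicular width
  ≥ 10 Å, at the Γ point; mass/inertia weighting uses each molecule's
  principal axes, with null-inertia axes (linear bodies, point bodies)
  dropped. The three acoustic zeros are removed by magnitude;
  remaining negative eigenvalues flag the structure as a saddle.
  Symmetry-constrained minima can genuinely be saddles with respect to
  symmetry-breaking distortions; `rank_polymorphs` excludes such
  structures with a flag rather than silently reporting them.
* Free energies: quantum form F = Σ[hν/2 + k_BT ln(1 − e^(−hν/k_BT))]
  or classical Σ k_BT ln(hν/k_BT), per molecule. G(T) = E_latt +
  F_vib(T) at the 0 K optimized cell; thermal expansion is not
  modelled (no quasi-harmonic volume dependence, no MD-averaged
  cells).

## Hirshfeld surfaces

* Promolecule densities are single-ζ Slater shells with Slater-rule
  exponents, spherically averaged. Only density ratios enter the
  weight w = ρ_in/(ρ_in + ρ_out), so this simple tabulation choice
  affects surface positions only weakly; the w = 0.5 isosurface is
  extracted by marching cubes (scikit-image) on a grid of 0.3 Å
  default spacing with the environment truncated 8 Å beyond the
  molecule's bounding box.
* Contact percentages classify each triangle by (nearest inside
  element, nearest outside element), symmetrized; they sum to 100 by
  construction of the area partition. d_norm and curvature properties
  are not computed.
* Hydrogen-rich planar molecules (benzene-like rings) legitimately
  show H···H as the single largest share even when π-stacked; the
  stacking signature appears as C···C overtaking C···H and as the
  fingerprint bright spot near half the interplanar spacing.

## Synthetic data: what it emulates, and what not

The generator produces every input the pipeline needs: toy rigid
molecules (a polar diatomic, a benzene-like planar ring), a planar
bicyclic 17-atom coumarin model built from standard bond lengths
(molar mass 146.14 g/mol), ground-truth packings, and synthetic powder
patterns. Patterns emulate a synchrotron capillary measurement of a
melt-crystallized film stabilized in a resin matrix: λ = 0.41064 Å,
fine uniform 2θ steps, pseudo-Voigt Bragg peaks, Poisson counting
noise (variance = intensity), and a broad Gaussian amorphous halo
centered near the main packing d-spacing with amplitude 20% of the
strongest peak. They do **not** emulate instrument aberrations beyond
a zero shift, texture/preferred orientation, multi-phase mixtures, or
2D detector effects.

Ground-truth packings are defined as the best structure of a small
seeded search under the bundled force field — realistic force-field
minima rather than hand-placed configurations. The "polymorph
analogues" used in the Hirshfeld checks are the lowest-energy packings
of the coumarin model found in the experimentally known cells and
space groups of each form; they share those forms' packing constraints
(the 3.98 Å stacking axis of the monoclinic form, the herringbone-
friendly orthorhombic cell of the stable form) but are minima of the
stand-in model, not the experimental structures.

Two scenario tiers exercise the whole pipeline end to end: "easy"
(polar diatomic, P2₁, Z′ = 1, free cell) and "fixed-cell" (planar
ring, P2₁, Z′ = 2, true cell supplied, deeper sampling because the
placement space doubles). The fixed-cell scenario uses the ring rather
than the diatomic deliberately: a crystal of polar diatomics has a
nearly homometric twin (every molecular dipole reversed) with
essentially identical energy and powder pattern, which makes a
ground-truth identity test ill-posed for that body; molecules with an
in-plane two-fold axis have no such twin. Passing these scenarios
shows the pipeline recovers planted structures under realistic noise
at desk scale; it does not show that the scaled-down search budgets
would suffice for a flexible molecule, for Z′ = 3, or for a real
blind-test landscape.

## Problem sizes used by the checks

The packaged checks run, per invocation: searches of 8–80 candidates
(free-cell diatomic ≈ 1.5 s/candidate, fixed-cell ring ≈ 2 s),
comparison clusters of 8–12 molecules, phonon supercells of 8–54
rigid bodies, and Hirshfeld grids of ~10⁵ points. These sizes were
chosen so the full suite completes in well under ten minutes of
single-CPU time while every code path runs at full fidelity.

## Known limitations

* No intramolecular flexibility anywhere (search, energy, refinement,
  phonons); the pipeline is for rigid or rigid-approximable molecules.
* No distributed multipoles, polarizability, exp-6 potentials, or any
  electronic-structure method; energy rankings inherit the accuracy
  ceiling of point-charge + LJ models, which is known to be
  insufficient for fine polymorph ordering.
* Single-phase powder refinement only; R factors from different
  weighting conventions than counting weights are not reproduced.
* The 14 supported space groups cover the common organic cases, not
  the full 230; non-standard settings, disorder, and partial
  occupancy are unsupported.
* Deduplication thresholds (fingerprint 0.05, RMSD 0.3 Å) are tuned
  for small rigid molecules; very large or very flexible systems
  would need re-calibration.
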