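# Methods

## Energy model

`ffcore` implements the gas-phase AMBER functional form: harmonic bonds
k_b(l−l₀)² and angles k_a(θ−θ₀)² (force constants absorb the conventional ½),
Fourier torsions Σ_n V_n/2·[1+cos(nω−γ_n)], and all-pairs Lennard-Jones plus
Coulomb nonbonded terms with 1–2/1–3 exclusions and per-torsion-type 1–4
divisors `scee`/`scnb`. There are no cutoffs and no periodic boundaries —
the engine exists for single-molecule torsional scans, not condensed-phase
simulation, so Ewald-type machinery is deliberately absent.

Conventions fixed here because file formats and downstream AMBER tools depend
on them:

* Coulomb prefactor 1/(4πε₀) = 332.0522173 kcal·Å/(mol·e²), the AMBER
  electrostatic constant; prmtop charges are stored multiplied by 18.2223.
* Lorentz–Berthelot combining: r_min,ij = r_i/2 + r_j/2, ε_ij = √(ε_i ε_j).
* Dihedral sign: looking down j→k, clockwise rotation of k–l relative to i–j
  is positive; values wrapped to (−180°, 180°]; reversal of the quadruple
  leaves the angle unchanged.
* Improper torsions evaluate identically to propers but never enter fitting.
* frcmod DIHE records are written with divider 1 and PK = V_n/2 (matching the
  prmtop `DIHEDRAL_FORCE_CONSTANT` convention); multi-term torsions use the
  negative-periodicity continuation convention.

Gradients are analytic throughout (bond, angle, torsion, nonbonded, and
flat-bottom dihedral restraints) and are tested against central finite
differences at relative 1e-6 on seeded random geometries. The restrained
minimizer is Cartesian L-BFGS-B, converged when the largest gradient
component falls below 1e-4 kcal/mol/Å; internal-coordinate machinery would
buy nothing at these system sizes and is not used. Restraint deviations are
always wrapped to (−180°, 180°] before the penalty is evaluated (in radians).

## Conformers and centroid selection

Conformers come from a pluggable embedding backend — RDKit ETKDG
(seed-deterministic) for real molecules, prebuilt geometries for fixtures —
and are minimized with the internal MM engine (an external semiempirical
minimizer can be slotted in through the same `minimize(conf) -> (conf, E)`
interface). Each minimized conformer is represented by two features: its
heavy-atom RMSD (Kabsch superposition) to the lowest-energy conformer and its
relative energy. Both columns are L2-normalized across the set — an all-zero
column is left at zero, degrading gracefully to the remaining feature — and
Ward linkage clusters the feature vectors. The dendrogram cut is the one
genuinely open design choice in this stage: the cut height is a configurable
fraction (default 0.25) of the maximum merge height, floored at one cluster
and capped at 10, which on well-separated ensembles reproduces the visually
obvious partition and is exercised against an exhaustive Ward-criterion
oracle at n = 6 in the tests.

Each cluster's lowest-energy member is its centroid. Centroids above the
retention window (default 3.5 kcal/mol, boundary inclusive — "retain
low-energy" is read as keep-at-threshold) are discarded; the global minimum
always survives. Boltzmann weights use k_B = 0.0019872041 kcal/mol/K at
T = 298 K and are invariant to constant energy shifts. Conformer-specific
charge sets are combined as q̄_i = Σ_k w_k q_i^(k); every set must carry the
same total molecular charge to 1e-6 e, which the average then conserves.

## Torsion selection

Candidates are all bonded paths i–j–k–l in one canonical orientation (the
lexicographically smaller type-quadruple reading). A candidate is retained
when the maximum pairwise wrapped dihedral difference across the centroid
set strictly exceeds the cutoff (default 30°; "exceeds" read strictly, so a
dispersion of exactly 30.0° is excluded). Pruning then removes:

* terminal torsions — an outer atom that is hydrogen or a heavy atom with a
  single heavy neighbour marks a quasi-free rotor;
* ring-contained torsions — the central bond is a ring bond, or one smallest
  ring (minimum cycle basis) contains all four atoms. A biphenyl-style
  inter-ring torsion therefore survives: its atoms are all ring atoms but its
  central bond is the rotatable inter-ring single bond;
* duplicate definitions on one central bond — the survivor is the most
  backbone-like, scored as the minimum over the two outer atoms of their
  graph distance to the nearest terminal heavy atom (larger = deeper in the
  heavy-atom framework; ties go to the lower canonical quadruple). This depth
  metric is this package's concrete stand-in for backbone-likeness.

The longest heavy-atom chain is found by exhaustive simple-path search with a
deterministic tie rule (lexicographically smallest sequence after
canonicalizing each path against its reversal); torsions whose central bond
lies on that chain are flagged backbone-connected.

## Fragmentation

Torsion regions are connected components of the significant central bonds
under shared-atom adjacency. Fragmentation is triggered when there are two or
more regions, or when the molecule exceeds 35 heavy atoms and a region is
localized to less than half of them (the threshold is a package default,
exposed in config). Fragments grow outward from a region to include every
atom within two bonds — the entire 1–4 environment of the region's torsions —
and then extend further through any boundary bond that is illegal to cut:
ring bonds, double bonds, bonds touching an exocyclic double bond, bonds
inside protected functional groups, or bonds closer than two bonds to a
region central bond. Protected groups (amide, ester, sulfonamide, nitro,
carboxylate, guanidinium) are matched as element/bond-order subgraph patterns
on the topology graph; the inventory is editable, and SMARTS strings define
the same vocabulary when an RDKit molecule is available. If no legal cut
exists the fragment is the whole molecule.

Each cut is capped by a methyl group: a carbon placed along the severed bond
vector at 1.526 Å with three hydrogens at tetrahedral positions (1.09 Å).
Mapped atoms keep their parent parameters and charges; cap atoms get generic
sp³ carbon/hydrogen parameters and zero charge — defensible because a
fragment is only ever used to scan and fit its own region's torsions, whose
bonded and 1–4 environment is preserved verbatim. Atom maps are bijective on
non-cap atoms and serialized as JSON with 0-based indices and a `caps` array.

## Scans and profile selection

Scans visit a uniform grid (spacing must divide 360°; default 20° → 18
points), restraining the scanned dihedral with a flat-bottom restraint
(500 kcal/mol/rad², ±0.5°) and relaxing everything else. The walk starts at
the grid point nearest the input dihedral and proceeds sequentially around
the circle, seeding each point from its neighbour's relaxed geometry —
propagating geometry suppresses the spurious discontinuities that independent
starts produce. Failed points are linearly interpolated and the profile
marked degraded. Profiles are shifted so their minimum is zero.

Scans are launched from every centroid; the survivor minimizes a composite
roughness score: RMS residual of a linear least-squares fit to the Fourier
basis {1, cos nθ, sin nθ : n ≤ 4}, plus 0.5 × the largest energy jump
between circularly consecutive points, plus 0.5 × the RMS circular second
difference. The weights and the order-4 basis are package choices (exposed in
config); every component scales linearly with energy, so selection is
invariant to the profile's overall scale. Ties go to the lowest centroid
index, and a degraded profile loses every tie.

## Fitting

The objective is L = Σ_g (Ẽ_MM(θ_g) − Ẽ_ref(θ_g))² with both profiles
mean-centered — centering eliminates the arbitrary offset between reference
and MM energy scales analytically and keeps L smooth (min-alignment would
make it piecewise). Fitting is type-based, as AMBER semantics require: the
parameters apply to every proper torsion sharing the target's atom-type
quadruple, and in full mode to the 1–4 pairs those torsions own. At frozen
scan geometries the MM profile decomposes into a parameter-independent base,
the fitted Fourier terms at precomputed dihedral angles, and the owned 1–4
Coulomb/LJ sums divided by scee/scnb — so the exact gradient is a few lines
of closed form, verified against finite differences at relative 1e-6.

Two modes: `torsion_only` fits the barrier heights V_n on a fixed periodicity
basis (default {1,2,3,4}; an amplitude driven to zero retires that
periodicity) with phases and scaling frozen bitwise; `full` adds the phases
γ_n and the type's scee/scnb. Bounds: V_n ∈ [0, 20] kcal/mol (a negative
amplitude is expressible as a 180° phase shift), γ_n ∈ [0°, 360°),
scee ∈ [0.5, 3], scnb ∈ [0.5, 4]. The inner minimizer is L-BFGS-B. Full mode
tries two starts — the current topology values and a closed-form start from
the phase-free linearization a_n cos nω + b_n sin nω (V_n = 2√(a²+b²),
γ_n = atan2(b, a)) — and keeps the better, which removes the phase
local-minimum failure mode; a seeded jittered retry covers optimizer
failures. The outer loop re-runs the MM scan with updated parameters to
refresh geometries and stops when the profile RMSD changes by less than
0.001 kcal/mol (default, max 10 cycles); with no scan callable the fit is a
single cycle on frozen geometries. A fit that would end worse than it
started returns the initial parameters with a warning. Components below
0.005 kcal/mol are pruned from the result. The configurable 0.05 step-scale
hint is carried in the spec for provenance but L-BFGS-B determines its own
step sizes.

Outputs merge per-torsion (and per-fragment, through the atom maps) results
into one frcmod and one parmed script keyed by parent atom types; identical
duplicate updates are deduplicated, and genuine conflicts on one type
quadruple are resolved last-fitted-wins (configurable, logged) — the merge
policy is a package construct since nothing forces two fragments to agree.

## Synthetic fixtures and what they do (not) show

The fixture set covers each decision point of the workflow: `butane_like`
(hexane-like united-atom chain; exactly one torsion survives pruning),
`rigid_ring` (all torsions ring-contained; the pipeline exits cleanly),
`biphenyl_like` (ring exclusion keeps ring-internal torsions out while the
inter-ring torsion survives), `amide_chain` (cleavage must not touch the
amide), and `two_region` (two disconnected torsion regions force
fragmentation). Force-field constants are physically plausible round numbers
(C–C 300 kcal/mol/Å² at 1.526 Å, angles 40 kcal/mol/rad² at 109.5°/120°,
V₃ = 1.4 kcal/mol chain torsions, LJ ε_C = 0.109 kcal/mol, scee 1.2 /
scnb 2.0) — they are not real GAFF2 assignments and do not need to be.

The mock reference backend is the internal MM engine running on a seeded
copy of the topology whose torsion barriers are perturbed by a uniform draw
in [1.0, 2.5] kcal/mol — one draw per atom-type quadruple, seeded by a stable
hash of the type so a fragment and its parent see identical perturbations.
Because AMBER parameters are type-based, a per-type perturbation is exactly
the kind of discrepancy a refit can represent, which is what makes
end-to-end recovery a sharp test: the pipeline must return the drawn values
to 1e-2 kcal/mol. What these fixtures deliberately do not emulate: electronic
effects a quantum reference would show (conjugation breaking at ring
twists, hyperconjugation), charge-model conformational dependence beyond the
supplied per-conformer sets, and profile noise other than seeded Gaussian.
Passing tests demonstrate the machinery — selection, scanning, optimization,
bookkeeping — is correct, not that any particular quantum chemistry level is
well reproduced.

Problem sizes throughout the suite (6–16 united-atom molecules, 3-conformer
ensembles, 12–18-point grids) are chosen so the full workflow runs in
seconds to a couple of minutes; every algorithm is size-independent and the
same code paths drive larger ligands.

## Known limitations

* Charges are consumed, never computed; AM1-BCC/RESP derivation is upstream.
* No quantum backend ships; the reference-backend slot accepts one (any
  object with `scan_point`), and tabulated (angle, energy) text profiles can
  stand in for external scans.
* Gas phase only: no PBC, no Ewald, no cutoffs.
* Ring-adjacent torsions can retain residual profile RMSE after fitting
  (~0.03 kcal/mol on the two-region fixture) because ring relaxation couples
  into the scan in ways a single torsion term cannot absorb; the fit still
  converges and reports the residual honestly.
* Macrocycle-aware ring handling and GROMACS/CHARMM export are out of scope.
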