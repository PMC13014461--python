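# torsionsmith

Automated refitting of AMBER/GAFF2 torsion parameters for small molecules.

Generic force fields assign torsion terms by atom type, and for many drug-like
ligands those generic terms misplace rotamer minima or barrier heights — errors
that propagate directly into conformational ensembles and binding free
energies. `torsionsmith` rebuilds the torsional part of the force field
per-ligand: it identifies the chemically significant rotatable torsions from a
conformer ensemble, optionally cuts the molecule into methyl-capped fragments
around them, drives restrained 360° dihedral scans against a reference
backend, and refits the Fourier torsion terms (and optionally the 1–4 scaling
factors) by bounded quasi-Newton least squares, emitting standard AMBER
`frcmod` / `parmed` / `mol2` outputs.

## The model

The molecular-mechanics energy is the standard gas-phase AMBER form

    V = Σ_bonds k_b (l − l₀)²  +  Σ_angles k_a (θ − θ₀)²
      + Σ_torsions Σ_n  V_n/2 · [1 + cos(n ω − γ_n)]
      + Σ_{i<j}  ε_ij [(r_min,ij/r_ij)¹² − 2 (r_min,ij/r_ij)⁶]
                 + q_i q_j / (4π ε₀ r_ij)

with 1–2 and 1–3 pairs excluded and 1–4 pairs divided by `scnb`
(Lennard-Jones) and `scee` (electrostatics). The quantities being fitted are
the Fourier components (V_n, n, γ_n) of selected torsions — and, in the full
fitting mode, that torsion type's `scee`/`scnb`.

The fitting objective is the mean-centered sum of squared differences between
the molecular-mechanics and reference torsional energy profiles, both obtained
from relaxed scans on a uniform dihedral grid (default 20°, 18 points) with
the scanned dihedral held by a flat-bottom restraint (500 kcal/mol/rad²,
±0.5° tolerance). At frozen scan geometries the profile is an explicit,
analytically differentiable function of the parameters, so L-BFGS-B receives
exact gradients; an outer loop re-runs the MM scan with updated parameters
until the profile RMSD change falls below 0.001 kcal/mol.

Significant torsions are found by clustering minimized conformers on
(heavy-atom RMSD, relative energy) features with Ward linkage, keeping
centroids within 3.5 kcal/mol of the minimum, and retaining torsions whose
wrapped dihedral dispersion across centroids exceeds 30° — after excluding
terminal-atom torsions, ring-contained torsions, and duplicate definitions on
one central bond. Disconnected torsion regions trigger fragmentation with
methyl capping; JSON atom maps carry fragment results back to the parent.

## Worked example

Fit the central torsion of the built-in hexane-like fixture against a mock
reference backend whose ground truth is known exactly (the internal MM engine
running on a seeded, torsion-perturbed copy of the topology):

```python
from torsionsmith.synthetic import make_fixture, mock_qm_backend
from torsionsmith.scan_engine import InternalMMBackend, make_grid, run_scan
from torsionsmith.torsion_fit import FitSpec, fit_torsion

mol = make_fixture("butane_like")
quad = (1, 2, 3, 4)
grid = make_grid(20.0)                       # 18 points over 360 deg

reference = run_scan(mock_qm_backend(mol.topology, perturbation_seed=3),
                     mol.topology, mol.conformations[0], quad, grid)
mm = InternalMMBackend()
result = fit_torsion(
    mol.topology, quad, reference, FitSpec(mode="torsion_only", basis=(3,)),
    mm_scan=lambda top: run_scan(mm, top, mol.conformations[0], quad, grid))
```

Output:

```
reference barrier  V3 = 3.2198 kcal/mol
fitted barrier     V3 = 3.2198 kcal/mol
profile RMSE 0.6431 -> 2.88e-08 kcal/mol in 2 outer cycles
```

The initial parameters (V3 = 1.4 kcal/mol) disagree with the reference
profile by 0.64 kcal/mol RMS; the fit recovers the reference barrier height
to 4 decimal places and flattens the residual to numerical noise.

The same workflow end to end, from the shell:

```bash
torsionsmith run --fixture butane_like --seed 2 --out run/
```

```
  conformers     ok (0.03 s)
  centroids      ok (0.00 s)
  selection      ok (0.00 s)
  fragmentation  ok (0.00 s)
  scans          ok (0.59 s)
  fit            ok (1.22 s)
  outputs        ok (0.00 s)

significant torsions: 1
  (1, 2, 3, 4)  RMSE 0.6290 -> 0.0000 kcal/mol
```

Each step persists its artifacts under `run/stepNN_*/` (prmtop, two-column
scan profiles, JSON); `torsionsmith resume run/ --from-step fit` recomputes
from any step, and `run/step07_outputs/` holds the merged `final.frcmod`,
`parmed.in`, `final.mol2` and atom maps. Real ligands enter through
`--topology mol.prmtop` with `--mol2` coordinates or `--smiles` for ETKDG
embedding.

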