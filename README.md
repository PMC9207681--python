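# memfield

Computational machinery for studying how a peripheral sterol-transfer
protein engages anionic membranes, exercisable entirely on synthetic
inputs. Three pillars:

1. **Mean-field electrostatic docking** (`memfield.meanfield`) — a
   linearized Poisson–Boltzmann solver for a fixed-charge protein above an
   impermeable membrane plane whose anionic lipids are laterally mobile.
   The free energy `F = F_el + F_ion + F_lip` (electrostatic field energy,
   ion translational entropy, lipid mixing entropy, all in kT relative to
   the protein-free uniform-membrane reference) is minimized
   self-consistently by conserving Langmuir density updates; protein
   orientations are scanned on a Fibonacci sphere × azimuth grid, ranked by
   adsorption energy, and the steady-state anionic density map is exported
   for seeded lipid placement.
2. **Trajectory analytics** (`memfield.analysis`) — membrane plane fitting,
   C-terminal-helix tilt/rotation orientation maps, residue–lipid contact
   probabilities (4 Å headgroup-oxygen / sidechain-N,O criterion) with
   multiplicities and shared-site statistics, Shrake–Rupley buried contact
   areas, strict-threshold membrane-embedding detection
   (>200 Å² / >150 Å²), and last-N-ns analysis windowing (default 720 ns).
3. **Transfer kinetics** (`memfield.kinetics`) — single-exponential FRET
   trace fitting with asymptotic standard errors, conversion to molecules
   transferred per carrier per minute (`rate = k · f_eq · DHE₀ / [carrier]`),
   and fold-change comparisons with propagated uncertainty.

`memfield.synth` generates every input the other stages need: bead proteins
with labeled segments and charged sites, symmetric lattice bilayers at a
44:23:23:10 composition (largest-remainder allocation; 2 × 200 sites → 400
lipids), trajectories with planted orientations and binding events, and
noisy exponential traces — all deterministic under a fixed seed.

## Numerical notes

The field solver uses a 19-point Mehrstellen (compact 4th-order) stencil
with a Numerov-consistent screening mass and a 6th-order source expansion;
the membrane surface-charge flux boundary reproduces the uniform
Gouy–Chapman mode exactly, lateral faces are periodic, and the top face is
Dirichlet. At a grid spacing of λ/2 (the default 256 Å box at 64³) the
solution matches the Yukawa point-charge and exponential-plane closed
forms to better than 2% pointwise. An optional nonlinear Boltzmann ion
mode (config `solver.nonlinear_ions`) is validated against the Grahame
equation.

## CLI

```bash
memfield synth bilayer|protein|traj|fret --seed N --out-dir d/
memfield dock --protein p.pdb --charges q.csv --config cfg.yaml \
    --n-dirs 72 --n-az 12 --out-dir d/        # poses.json, density.csv,
                                              # placement.csv
memfield analyze orientation|contacts|embedding \
    --top top.pdb --traj traj.pdb [--window-last-ns 720] --out-dir d/
memfield kinetics fit --trace trace.csv --dhe-um 23 --stard4-um 1 \
    --f-eq 0.5
memfield kinetics fold-change --fit-a a.json --fit-b b.json
```

Every CLI table is CSV with a `# provenance:` JSON header (command, seed,
config hash, version); identical config + seed reproduce byte-identical
bodies. Structures and trajectories are plain (multi-model) PDB;
configuration is YAML with strict unknown-key rejection (see
`memfield.core.config` for all keys and defaults).

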