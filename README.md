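# nucleomc

Coarse-grained Monte Carlo model of a bacterial cell: one confined DNA
polyanion, self-associating cationic protein dimers (an H-NS surrogate),
charged spherical crowders (ribosome surrogates) and explicit monovalent
counterions, all inside a spherical cell of radius 100 Å.

Bacterial nucleoids are condensed without histones or a nuclear envelope.
This package lets you ask, at the level of a primitive-model electrolyte,
how three ingredients conspire to condense and stabilize a model genome:
electrostatic DNA–protein complexation, weak protein self-association, and
competition from negatively charged crowders that can strip DNA-binding
proteins off the chain.  It is aimed at polymer/biophysics researchers who
want a transparent, fully reproducible desk-scale simulation of these
effects rather than a black-box molecular-dynamics stack.

## Model

The total energy (in kT) is

    U = U_nonbond + U_bond + U_ang + U_ext

* `U_nonbond`: over all pairs, hard-sphere + Coulomb
  `u(r) = ∞ (r < Ri+Rj), l_B z_i z_j / r` with Bjerrum length
  `l_B = e²/4πε0ε_r kT = 7.15 Å` (water, 298.15 K); plus, over protein
  monomer pairs, a Lennard-Jones self-association
  `4ε_pp((σ/r)¹² − (σ/r)⁶)` with ε_pp = 0–2 kT.
* `U_bond`: harmonic bonds `(k_bond/2)(r − r0)²`, k_bond = 0.4 N/m,
  r0 = 5 Å (DNA chain and each dimer).
* `U_ang`: DNA angular stiffness `(k_ang/2)(α − 180°)²`,
  k_ang = 3.4·10⁻²⁴ J/deg².
* `U_ext`: hard spherical confinement of every particle center.

Sampling is canonical Metropolis Monte Carlo with single-particle moves
(100× more frequent), rigid chain translations, and a bias-corrected
slither (reptation) move for the DNA.  Observables include the
radius-of-gyration distribution P(RG) (mean-distance estimator
`(1/N)Σ|r_i − r_CM|`), RMS end-to-end distances, radial distribution
functions normalized for spherical confinement, and Bjerrum-criterion
effective crowder charges.  See `docs/methods.md` for the complete
specification of conventions and uncertainties.

## Worked example

Simulate 60 protein dimers with their counterions (no DNA) and measure the
intra-dimer separation, then the DNA + dimers system and its chain size:

```python
from nucleomc import (SystemConfig, McSchedule, ForceField, MoveSet,
                      build_system, run_mc, subbatch_errors)
from nucleomc.observables import intra_dimer_separation, rg_series

cfg = SystemConfig(n_dna=0, n_hns=60, eps_pp=0.0,
                   mc=McSchedule(equil_sweeps=500, prod_sweeps=5000, seed=4))
res = run_mc(build_system(cfg), ForceField.from_config(cfg), cfg.mc)
sep, err = intra_dimer_separation(res.trajectory)
print(f"intra-dimer separation: {sep:.2f} +- {err:.2f} A")

cfg = SystemConfig(n_dna=120, n_hns=60, eps_pp=0.0,
                   mc=McSchedule(equil_sweeps=2000, prod_sweeps=20000, seed=6))
res = run_mc(build_system(cfg), ForceField.from_config(cfg), cfg.mc)
rg, err = subbatch_errors(rg_series(res.trajectory), 10)
print(f"DNA radius of gyration: {rg:.1f} +- {err:.1f} A")
```

Output:

```
intra-dimer separation: 5.70 +- 0.00 A
DNA radius of gyration: 52.1 +- 1.2 A
```

The dimer bond stretches past its 5 Å equilibrium length because the two
+1 monomers repel (≈1.4 kT at contact); switching on ε_pp = 2 kT pulls the
pair toward the LJ minimum at ≈6.5 Å instead.  The 120-monomer DNA in the
presence of 60 dimers (charge-ratio unity) relaxes to a mean
radius of gyration of ≈50 Å — moderately condensed relative to the chain
with counterions only (≈58 Å), because complexation only partially
neutralizes the chain.

Or from the shell:

```sh
nucleomc scenario emit dna_hns --eps-pp 2 --out cfg.toml
nucleomc run --config cfg.toml --seed 1 --out run1/
nucleomc analyze run1/
```

`run` writes an extended-XYZ trajectory (readable by OVITO/VMD), an energy
table, an HDF5 checkpoint and a manifest with checksums; `analyze` writes
P(RG), RDF curves for every particle-kind pair present, effective-charge
and summary TSV tables.

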