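# Methods

## The model

`nucleomc` simulates a minimal bacterial-cell model: a spherical cell of
radius `Rcell = 100 Å` containing

* one **DNA chain** — 120 hard spheres of radius 2 Å and valence −1,
  connected by harmonic bonds `U_bond = (k_bond/2)(r − r0)²` with
  `k_bond = 0.4 N/m` and `r0 = 5 Å`, plus an angular stiffness
  `U_ang = (k_ang/2)(α − 180°)²` with `k_ang = 3.4·10⁻²⁴ J/deg²` at every
  interior monomer;
* **protein dimers** (an H-NS surrogate) — pairs of +1 hard spheres of
  radius 2 Å joined by the same harmonic bond, 60 dimers at charge-ratio
  unity with the DNA.  Protein monomers additionally interact through a
  Lennard-Jones potential `4ε_pp((σ/r)¹² − (σ/r)⁶)` that models protein
  self-association, with `ε_pp` between 0 and 2 kT;
* **crowders** — hard spheres of radius 10 Å (ribosome surrogates), neutral
  or negatively charged; an integer valence `Z_crow` is derived from a
  surface charge density σ in e/nm² as `round(σ·4π(R/10 Å)²)`;
* **explicit counterions** — ±1 hard spheres of radius 2 Å.  Their numbers
  are always derived from exact electroneutrality (positive ions neutralize
  DNA + crowders, negative ions neutralize the protein charge), never taken
  from input.

Electrostatics is the primitive model: `u(r) = l_B z_i z_j / r` in kT beyond
hard-sphere contact, infinite inside, with the solvent entering only through
its relative permittivity ε_r = 78.4 at T = 298.15 K.  The Bjerrum length
`l_B = e²/(4π ε0 ε_r kT) = 7.15 Å` is always recomputed from ε_r and T.
There is no interaction cutoff: the cell is finite and non-periodic
(N ≲ 1500), so all pairs are summed directly.  Confinement acts on particle
*centers* (`|r_i| < Rcell`), exactly as the external-potential definition
states, so a particle surface may protrude.

Internal units: lengths in Å, energies in kT at 298.15 K, angles in degrees.
The fixed conversions are `k_bond = 0.9717 kT/Å²` and
`k_ang = 8.26·10⁻⁴ kT/deg²`.

## Sampling

Canonical-ensemble Metropolis Monte Carlo with three trial moves:

1. **single-particle translation** — uniform in a cube of side 2·amplitude;
   attempted 100× more often than the other move types;
2. **rigid chain translation** — applied to the DNA and to each dimer;
   intra-chain terms are invariant and skipped in the delta;
3. **slither (reptation)** — DNA only: a randomly chosen end monomer is
   regrown at the opposite end.  The trial bond length is drawn from
   p(r) ∝ r²·exp(−β k_bond(r−r0)²/2), the trial chain angle from
   p(α) ∝ sinα·exp(−β k_ang(α−α0)²/2), the azimuth uniformly.  Because the
   generation densities carry the full Jacobian (r², sinα), the bond and
   angle Boltzmann factors cancel from the acceptance ratio analytically and
   only the nonbonded + confinement energy enters the exponent.  The bond
   sampler's rejection envelope is truncated at r0+5σ; the probability mass
   beyond it is ≈10⁻⁷ and the resulting bias is far below statistical
   resolution.

Single-particle moves carry two amplitudes — one for chain monomers, one
for free particles — tuned independently toward 30–50% acceptance: bond
constraints cap the useful monomer step near the bond length while free
ions tolerate much larger steps, and a single shared amplitude tuned on the
global rate (dominated by the free-ion majority) would effectively freeze
the chain's local dynamics.  Tuning happens during equilibration only;
amplitudes are frozen for production, preserving detailed balance where it
matters.  "Sweeps" count trial moves per particle.  Production is
divided into sub-batches (default 10); uncertainties are standard errors of
block means.  Energies are tracked by accumulated per-move deltas and
cross-checked against a full recomputation at every sampling stride; a
drift beyond 10⁻³ kT aborts the run with a checkpoint (observed drift after
10⁶ accepted moves is below 10⁻⁶ kT, which the test suite asserts).

All randomness flows from one seed: chunk seeds are derived from
(seed, chunk counter), which also makes checkpoint restarts bit-identical
to uninterrupted runs.

## Observables

* **Radius of gyration** — two estimators on purpose.  The *mean-distance*
  form `(1/N)Σ|r_i − r_CM|` is the definition behind the size distributions
  P(RG) and their reported means.  The *RMS* form
  `sqrt((1/N)Σ|r_i − r_CM|²)` is used only for the shape ratio below.
* **Shape ratio** — RMS(Ree)/RMS(Rg) over frames, the >1 orientation
  (discrete rod: `sqrt(12(N−1)/(N+1))` ≈ 3.46 at N=120; ideal coil ≈ 2.45).
* **RDFs in spherical confinement** — pair-distance histograms normalized
  by the analytic distance distribution of two independent uniform points
  in the sphere (CDF `x³ − (9/16)x⁴ + x⁶/32`, x = r/Rcell), so a
  non-interacting system gives g(r) = 1 identically; the test suite asserts
  this self-consistency.  Same-kind pairs are counted once.  Default bin
  0.25 Å resolves contact peaks; P(RG) uses 2 Å bins.
* **Effective crowder charge** — per frame, a positive counterion is
  *condensed* when its center lies within `R_crow + 7 Å` of a crowder
  center (7 Å ≈ the Bjerrum length; shell width configurable as
  `zeff_shell`).  Each condensed ion is assigned to its nearest qualifying
  crowder and counted once; ties break to the lower crowder index.
  `Z_eff = Z_crow + ⟨condensed ions⟩/N_crow` with sub-batch errors.
  The counting convention matters at the ±0.5 e level: measuring the 7 Å
  shell from the crowder surface to the ion *surface* (center cutoff
  R+7+R_ct = 19 Å) raises Z_eff for the Z_crow=−5 system from ≈−3.0 to
  ≈−2.3.  The center-based convention is the package default.

## Initial configurations

Random sequential insertion, deterministic per seed: the DNA grows as a
connected non-overlapping walk (bond length r0, directions drawn from the
angular Boltzmann weight, relaxed to uniform near the wall), dimers as
2-step walks, then crowders and ions uniformly.  Packing failure after a
bounded number of attempts raises an error reporting the achieved fraction.
Equilibration erases the initial conformation; only validity matters.

## Scenarios and problem sizes

`scenarios.reference_scenario` emits every studied composition from the
reference table (DNA alone, neutral-chain reference, DNA+crowders,
DNA+dimers, the full mixture, dimers alone and dimers+crowders, and
crowder-radius variants), over the grids Φ ∈ {0, 0.06, 0.16, 0.20},
σ ∈ {0, −0.04, −0.08, −0.40, −0.80, −1.20} e/nm², ε_pp ∈ {0, 1, 2} kT.
Note σ = −0.04 and −0.08 e/nm² both round to Z_crow = −1 at R_crow = 10 Å,
so the six densities resolve to five distinct compositions.
Scale `"full"` carries the full-length schedule (2·10⁶ + 6·10⁶
sweeps); scale `"reduced"` (2000 + 20 000 sweeps) gives desk-scale runs in
minutes.  Reduced scale shrinks *only* the sampling length, never particle
counts, charges or potentials, so observables stay comparable with larger
error bars.  Scenario seeds are sha256-derived from the scenario label, so
grids are reproducible without a seed registry.

The desk-scale reproduction script (`scripts/acceptance.py`) uses
1000–6000 equilibration and 10 000–40 000 production sweeps per system
(240–600 particles).  Equilibration lengths follow the measured relaxation
of the chain size in the crowded cell (≈10⁴ sweeps); at these sizes the
dimer separation and condensation counts are stable to ~1% across seeds
and the chain-size means to a few percent.

## What the reduced runs do and do not show

The reduced schedules reproduce equilibrium *local* quantities (intra-dimer
separations, counterion condensation shells, contact peaks of RDFs) and
chain-size means to a few percent.  Slowly relaxing collective modes — the
approach of the full P(RG) distribution shape to its long-run limit, or the
partitioning kinetics of dimers between DNA and highly charged crowders —
carry larger residual autocorrelation at this length: sub-batch error bars
on chain-size means are honest only up to a factor ~2, and direction-style
comparisons (condensation on raising ε_pp, dissociation on raising σ) are
the appropriate reading.

Assembly of the self-associating DNA–protein complex from a dispersed start
is nucleation-limited: its onset varies by seed over more than 10⁴ sweeps.
Stability questions are therefore probed with a staged protocol — assemble
the complex once without crowders, insert crowders and their counterions
into that configuration (`insert_free_particles`), and compare
continuations that differ only in ε_pp.  A continuation either holds the
complex together (ε_pp = 2 kT, ~95 of 120 protein monomers in DNA contact)
or releases it within a few thousand sweeps (ε_pp = 1 kT with σ = −1.2
e/nm² crowders, decaying to ~10 contacts); dissociation is fast because it
needs no cooperative nucleation.  The model itself also idealizes aggressively:
sizes are not to biological scale, the protein is two beads, crowders are
smooth spheres, and there is no added salt beyond the counterions.

## Numerical choices

* Hard-core overlap and cell escape are detected geometrically *before* any
  potential evaluation and reported as an infinity sentinel; no
  floating-point overflow path exists.
* The LJ size parameter defaults to σ = 5.8 Å, placing the LJ minimum at
  2^{1/6}σ ≈ 6.5 Å — the observed intra-dimer spacing under strong
  self-association.  The bonded intra-dimer pair feels the LJ term by
  default (`lj_intra`), without which that spacing would not be imposed;
  both are configurable.
* ε_pp is specified in units of kT at 298.15 K.
* Metropolis exponentials are evaluated only for ΔU ≤ 500 kT; larger
  deltas are rejected outright.
* The degenerate zero-length bond vector in an angle evaluation raises an
  error rather than returning a silent value.

## Known limitations

* No periodic boundaries, no implicit-salt (Debye–Hückel) mode, no
  sequence-specific DNA, no forces/gradients (Monte Carlo only), no
  Ewald summation (not needed in a finite cell).
* The compiled kernels and the numpy reference implementation are kept in
  lock-step by the test suite; only the kernels are used in production
  runs.
* Checkpoint files are HDF5 and are the only non-text artifacts the
  package writes.
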