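# Methods

`micellekit` simulates the self-assembly of amphiphilic block copolymers
into single spherical micelles with an implicit-solvent, coarse-grained
bead-spring model, and measures the equilibrium aggregation number and the
structural observables of the resulting aggregate.  This note records the
model, the protocol, every numerical choice that was genuinely open, and
the limits of what desk-scale runs can and cannot show.

## Model

**Architecture.**  A copolymer is a linear hydrophobic block of `NB` beads
(type B) bonded to a hydrophilic block of `NA` beads (type A).  The
hydrophilic block is a regular dendron: one root spacer of `Ns` beads
attached to the hydrophobic chain end; for `g` generations, the terminal
bead of each spacer branches into `q` child spacers.  Hence
`NA = Ns (q^(g+1) - 1)/(q - 1)` for `q > 1` and `NA = Ns (g+1)` in the
linear limit `q = 1` (also `g = 0`).  The tree-shape convention near the
junction (root spacer bonded bead-to-bead to the B chain end; branch
points are spacer termini) is a documented convention; the bead count is
fixed by the formula regardless.

**Interactions** (reduced units: `sigma_BB = 1` length, `epsilon = 1`
energy, `kBT = 1`, unit masses, `dt = 0.01`):

* WCA excluded volume between all pairs, cutoff `2^(1/6) sigma_pair`;
  `sigma_AA = sigma_AB = 0.95`, `sigma_BB = 1`, counterions use
  `sigma = 1` against every partner.  Bonded pairs are not excluded
  (Kremer-Grest convention; equilibrium bond length ~0.97).
* FENE bonds, `kbond = 30`, `r_inf = 1.5`.  A bond reaching `r_inf` is a
  hard error, never silently clipped.
* Hydrophobic attraction between B-B pairs only: depth `eps_attr`
  constant inside the WCA cutoff, `cos^2` shoulder of width `wc`, zero
  beyond.  `eps_attr` sets the hydrophobicity, `wc` its range; both are
  the free parameters of the model.
* Bare Coulomb, `V = kBT lambda_B z1 z2 / r`, `lambda_B = 2` (water at
  room temperature; the physical mapping `lambda_B = 0.71 nm` implies
  `sigma = 0.355 nm` and is recorded as metadata only).  Quenched
  polyelectrolyte coronas carry one elementary charge per A bead;
  monovalent counterions restore exact electroneutrality.

**Electrostatics solver.**  Single-micelle systems carry at most a few
thousand charges, so the production path is a direct all-pairs sum under
open boundaries.  A standard Ewald sum (erfc-screened real space, tin-foil
reciprocal space, Gaussian self term) under cubic periodic boundaries is
provided and is cross-validated against the direct sum on compact neutral
clusters to 1e-4 relative; it exists as a correctness oracle, not as the
production path.

**Confinement.**  Open-boundary runs use a spherical harmonic wall
(`wall_k = 100 eps/sigma^2`) beyond radius `R_conf`, which plays the role
of the finite periodic box: it fixes the volume accessible to escaped
molecules and free counterions.  Default
`R_conf = 6 (2 p r0)^(2/3)` — six times the radius of the initialization
sphere.  A harmonic wall was chosen over a WCA-type wall because it is
nonsingular for beads that start beyond it (overlapping random inits) while
confining equally well: thermal excursions past the wall are
`~sqrt(kBT/wall_k) = 0.1 sigma`.

**Forces kernel.**  One all-pairs O(N^2) numba kernel evaluates WCA +
attraction + Coulomb, plus loops for bonds and the wall.  At the problem
sizes this package targets (N <= ~2000) it integrates thousands of steps
per second on one core, so no neighbor-list machinery is used; tests
verify it against an independent pure-numpy brute-force sum to 1e-10 and
against central finite differences of the energy to 1e-5 relative.

## Dynamics

Langevin dynamics `m x'' = f - gamma v + sqrt(2 gamma kBT) eta` with the
BAOAB splitting: half-kick, half-drift, exact Ornstein-Uhlenbeck velocity
refresh, half-drift, half-kick.  At `gamma = 0` this is exactly velocity
Verlet (validated by energy conservation of a bond oscillator: secular
drift < 1e-4 over 1e4 steps); at `gamma > 0` it samples the canonical
distribution accurately at `dt = 0.01` (validated by equipartition and by
the positional variance of a harmonic trap).  Default `gamma = 1`
(standard for Kremer-Grest reduced units; equilibrium observables are
friction-independent).  Frozen beads have forces and velocities zeroed
each substep and are excluded from temperature estimators.

Steepest descent removes initial overlaps: force-capped displacement
(default cap 0.01 sigma) with backtracking halving on energy increase, so
the accepted energy trace is non-increasing; termination at
`max |f| < force_tol` or the step budget.

## Single-micelle protocol

1. **Initialization.**  Each molecule is laid out fully stretched (bond
   length 0.97) along a random direction, hydrophobic block pointing
   inward, and shifted radially by `rshift = (2 p r0)^(2/3) xi` with
   `xi ~ U(0,1)`, `r0 = 1.1`.  A 0.01-sigma jitter breaks the exact
   overlap of sibling dendron branches.  Counterions start uniform in the
   confining sphere.
2. **Overlap removal** by steepest descent (a second pass with a halved
   displacement cap runs if large forces remain), followed by a brief
   reduced-time-step ramp so residual tight contacts unload gently.
3. **Frozen-corona stage** (default 500 steps): hydrophilic beads pinned,
   core and counterions relax inside the scaffold.
4. **Core seeding** (default `k = 0.15 eps/sigma^2`, cap 8000 steps): a
   weak central drift force on hydrophobic beads only, held until the
   core cluster analysis reports a single cluster.  *Why:* the
   initialization scatters the hydrophobic blocks over a region an order
   of magnitude wider than the attraction range; unbiased coarsening of
   the resulting sub-clusters is diffusion-limited and needs ~1e6 steps
   (we measured 12 -> 8 clusters over 6e4 steps at p = 20) — far beyond
   desk scale.  The drift assembles the single micelle that the protocol
   is designed to interrogate, acts on no corona or counterion degree of
   freedom, and is switched off before the warmup, so the measurement
   window is unbiased.  Realizations whose core still is not a single
   cluster at the cap simply proceed and are flagged by the split
   analysis.
5. **Warmup** (default 2500 steps) and **production** (default 5000
   steps, sampling every 50) under unbiased dynamics.

A realization occasionally snaps a FENE bond during the early relaxation
of a dense random packing; such attempts are discarded and re-drawn with a
derived seed (at most 3 attempts).  Production-stage bond breaks abort.

**Stationary window and flags.**  Averages are taken over the trailing
half of the production frames.  Stationarity check: 5 block means, first
vs last within 2 combined standard errors.  A realization is *split* when
the mean number of molecules outside the largest core cluster over the
window is >= 2 — transient single-molecule evaporation near equilibrium is
normal and is not a split.  It is *anisotropic* when the mean asphericity
exceeds 0.1.

**Sweep.**  For each `p` in the grid, `n` realizations run with seeds
derived from `(master_seed, p, index)` via `numpy.random.SeedSequence`
(independent and parallelizable).  Split realizations are excluded from
the per-`p` means but counted.  `p_eq` is the argmin of the mean energy
per molecule; when the next smaller `p` lies within one combined standard
error, the smaller `p` is preferred (cheaper, safely spherical).  A
minimum at the grid boundary and an asphericity argmin more than one grid
step away each raise explicit warnings.

## Observables

* Radius of gyration: rms distance from the subset centroid.
* Shape: gyration-tensor eigenvalues `l1 >= l2 >= l3`; asphericity
  `A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2]`,
  dimensionless in [0, 1]; this normalized form coincides algebraically
  with the relative shape anisotropy `kappa^2`, and both are exported.
  Size-independence makes per-`p` comparisons scale-free.  Subsets of
  fewer than 3 beads return zeros by convention.
* Radial density profiles: shell-normalized number densities per species
  around the center of mass of the largest core cluster (so escapees do
  not shift the center); the integral of `rho` times shell volume equals
  the species count exactly when `r_max` covers all beads (the default).
* Counterion partitioning: the corona boundary is the radius enclosing a
  percentile (default 95%) of the hydrophilic beads; `Qin` is the
  time-averaged fraction of counterions inside it, and the net charge
  follows exactly as `Znet = (1 - Qin) * n_counterions`.  Both the
  boundary definition and the percentile are reported with the result.
* Scaling fits: ordinary least squares of `ln y` on `ln x` (slope,
  intercept, slope standard error).

## Theory references

The interfacial free energy per molecule
`F_surface = gamma_surf (NB/phi_B)^(2/3) p^(-1/3)` is evaluable; the
corona and core free-energy terms have no universal closed form and are
represented instead by their minimization outcomes: a table of exact
rational scaling exponents (SCF and scaling theory, neutral and ionic,
linear and dendritic coronas), each entry carrying an anchor string, plus
the logarithmic aggregation law `p_eq = (alpha ln(beta NA))^(-6/5)`
(natural log — the base only rescales `alpha`; `alpha`, `beta` are free
inputs).  The Manning parameter `Gamma = lambda_B / l_charge` evaluates to
2 for this model's fully charged coronas with unit charge spacing, i.e.
roughly half the counterions condense.

## What desk-scale runs show, and what they do not

All defaults above are sized so that a full sweep runs in minutes on one
core.  Within that budget the protocol produces: reproducible
energy-per-molecule curves (realization-to-realization spread ~0.1-0.5
eps), correct thermostat statistics, correct charge bookkeeping, and
density profiles with clear core-corona separation.

Two caveats follow from the time-scale compression:

* For strongly cohesive neutral parameter sets (e.g. `wc = 1.6`,
  `eps_attr = 1.0`, `NA = 25`, `NB = 5`), the energy per molecule of the
  *intact* micelle decreases monotonically with `p` throughout the
  accessible range (measured through p = 60, and confirmed statistically
  unchanged under 4x longer production): the corona contact energy at
  `kBT = 1` is far softer than the core surface term (~90 p^(-1/3)
  eps/mol).  The interior minimum that full-scale studies of this system
  report arises from stationary states in which the overgrown micelle has
  split or grown anisotropically — activated events on ~1e6-step
  timescales that desk-scale production cannot nucleate.  The sweep then
  honestly reports a boundary minimum with its warning.
* Charged coronas add a genuinely energetic (electrostatic) penalty that
  grows with `p`, so ionic sweeps resolve interior minima directly at
  desk scale; ionic runs use `gamma = 0.3` (equilibrium observables are
  friction-independent, and counterion migration from the confining
  sphere into the corona — the slowest relaxation — speeds up as
  `1/gamma`).  The counterion fraction inside the corona, `Qin`, is not
  a property of the micelle alone: it balances electrostatic binding
  against the translational entropy of the *accessible free volume*, so
  its absolute value depends on `R_conf` (the box-size analog).  Reported
  `Qin` values are therefore tied to the stated default confinement.

The synthetic systems the protocol generates emulate monodisperse,
quenched-charge copolymers in a structureless implicit solvent at fixed
temperature.  They do not emulate: solvent hydrodynamics, salt,
pH-dependent (annealed) charging, polydispersity, or micelle-micelle
interactions; passing tests say nothing about those features of real
systems.
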