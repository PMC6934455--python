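# Methods

`morphmd` models the formation of a covalent bond inside a classical MD
simulation — the use case being covalent peptide–protein conjugation, e.g.
an electrophilic chloroacetamide warhead on a peptide alkylating a target
cysteine thiolate.  Classical force fields cannot change bonding patterns,
so the package implements the dual-topology switching protocol: two
complete parameter sets (noncovalent reactant, covalent product) are kept
loaded, a stochastic distance-gated trigger decides *when* the reaction
starts, and an adiabatic interpolation carries the system from one
parameter set to the other.

## The reactive protocol

1. **Pre-phase.** Conventional Langevin dynamics of the reactant.
2. **Watch loop.** The trajectory is recorded in fixed-length segments;
   full restart checkpoints (coordinates, velocities, RNG state) are saved
   at a regular interval (defaults mirror the production scale: 1-ns
   segments, 1-ps checkpoints).  After each segment the
   nucleophile–electrophile distance series is scanned in frame order:
   every frame with d < r_c (capture radius, default 3.3 Å) draws an
   independent Bernoulli with acceptance probability p0 (default 0.1).
   The first success selects its checkpoint as the initial state of the
   reaction.  The rejection gate deliberately slows the modelled reaction
   relative to conformational dynamics; no attempt is made to reproduce
   the real (hour-scale) rate.
3. **Morph.** Over a switching window T_rxn (default 2 ns) divided into
   equal update intervals (default 10 ps), the effective parameter set is
   regenerated at the start of each interval at the current value of the
   switching variable λ:
   - bonded terms present only in the reactant scale as (1 − λ)·k, terms
     present only in the product as λ·k.  Vanishing/appearing *bonds* are
     carried as weight-scaled harmonic distance restraints and swapped
     for native terms at the endpoints; angles and dihedrals are carried
     as force-constant-scaled native terms (for the harmonic forms used
     here the two realizations are identical term by term);
   - partial charges mix linearly, q(λ) = (1 − λ) q_R + λ q_P;
   - atom pairs whose exclusion / 1–4 status differs between the
     endpoints have their pair nonbonded interaction (LJ + Coulomb)
     scaled by the linearly interpolated endpoint factors.  This replaces
     an engine-specific bookkeeping workaround with a native per-pair
     mechanism of identical contract;
   - equilibrium values (r0, θ0) never move; only force constants and
     charges ramp.
   λ(t) is linear (t/T_rxn) or sigmoidal (cubic smoothstep 3u² − 2u³).
   Both shapes share the endpoints, so the final interval runs under the
   product topology itself and the post-phase continues seamlessly.
4. **Post-phase.** Conventional dynamics of the product.

The same seed reproduces the entire protocol bit for bit; checkpoints
store the RNG state, so resuming from a restart replays the original
continuation exactly.

## Engine

A deliberately small but exact engine: harmonic bonds and angles
(E = k(x − x0)², the constant absorbs the ½), cosine dihedrals
(V_n/2)(1 + cos(nφ − γ)), 12-6 LJ in rmin/ε form with Lorentz–Berthelot
combination, Coulomb with 1–4 divisors 1.2 (electrostatic) and 2.0 (vdW).
Internal units: Å, ps, amu, kcal/mol, radians, elementary charges;
k_B = 0.0019872041 kcal/mol/K.

Numerical choices:

- **Truncation.** Atom-based cutoff (default 9 Å); Coulomb is
  force-shifted and LJ energy-shifted to zero at the cutoff, so both
  energy and forces are continuous as pairs cross r_c.  (Plain truncated
  LJ gives a systematic ~2×10⁻³ NVE drift from crossing discontinuities,
  incompatible with the conservation targets; the shift changes forces
  not at all and pair energies by ≤ ε·10⁻²).  No Ewald summation: at the
  box sizes this package targets, mesh electrostatics would dominate the
  cost without changing any of the quantities the tests assert.
- **Periodicity.** Orthorhombic minimum-image boxes only.
- **Integrator.** BAOAB Langevin splitting; at zero collision frequency
  it reduces exactly to velocity Verlet.  Default friction 2 ps⁻¹,
  target 293 K.
- **Constraints.** SHAKE with corrections along the start-of-step
  reference bond directions plus the corresponding velocity impulse, and
  RATTLE velocity projection; this combination conserves the energy of a
  free rigid rotor to machine precision.  Bonds are constrained only when
  flagged in the topology *and* enabled in the engine configuration.
  Default timestep 1 fs with constraints off; the conventional rigid-H
  protocol (all X–H bonds plus rigid three-site solvent, 2-fs step) is
  what the benchmark experiments use.
- **Barostat.** Isotropic Berendsen-style weak coupling (τ_p 1 ps,
  compressibility 4.5×10⁻⁵ bar⁻¹).  Weak coupling does not generate the
  true NPT ensemble; only mean-pressure behavior is asserted.
- **Neighbor list.** Verlet list with a 2 Å skin, rebuilt on a
  max-displacement criterion from an O(N²) numba pass; adequate to a few
  thousand atoms.
- **Pressure.** Virial form P = (N k_B T + W/3)/V with the pairwise
  virial W = Σ r_ij·f_ij accumulated per term.

## The synthetic model system

`fixtures.build_sn2_fixture` generates a desk-scale S_N2 conjugation
system: a thiolate-like nucleophile fragment (CH₃S⁻, net −1), a
chloroacetamide-like substrate (leaving atom L bonded to the
electrophilic carbon, plus an amide head group), a neutralizing
counterion, and a box of three-site water-like solvent placed on a
jittered lattice with orientation retries to avoid clashes.  Both
endpoint topologies keep the same atom set — after the reaction L
persists as a free −1 anion.  The morph map is derived from the two
endpoints by `build_morph_map` itself, so the generator and the analysis
machinery can never disagree.

Parameter values are plausible textbook magnitudes (bond k 227–570
kcal/mol/Å², LJ ε 0.016–0.27 kcal/mol, water charges −0.8/+0.4, TIP3P-like
geometry), *not* a fitted force field.  The electrophilic carbon carries a
partial positive charge (+0.15 reactant, +0.18 product), as the chemistry
dictates; the leaving atom goes from −0.25 to −1.0 across the reaction.
Both endpoints are exactly neutral.

**The proximity tether.** Real conjugation waits hundreds of nanoseconds
for a sub-capture-radius approach; that is unreachable on a desk.  The
tether — a flat-bottom harmonic restraint between the reactive atoms,
onset 3.2 Å, k = 10 kcal/mol/Å² — stands in for the noncovalent-complex
preorganization that holds the warhead at reactive proximity.  The onset
sits just inside the capture radius deliberately: with the S/C LJ contact
distance near 3.9 Å plus a desolvation penalty, any looser tether leaves
sub-3.3 Å approaches as rare activated events (tens of picoseconds to
never, seed-dependent), defeating the tether's purpose.  With the tether,
contact is routine and *when* the reaction starts is governed by the
Bernoulli gate alone.  Consequence: trigger *statistics* are validated on
synthetic distance series, and tethered MD runs validate the protocol
mechanics and energetics, not approach kinetics.

What the generator does not emulate: real protein structure, fitted
charges/LJ (the real system's parameters are inputs, not outputs, of this
package), mesh electrostatics, and the µs time scales of the original
study.  Tests passing on the fixture therefore demonstrate the
correctness of the machinery — bookkeeping, energetics, statistics,
determinism — not biological accuracy.

## Benchmark experiments and their scale

`benchmarks.run_adiabaticity_benchmark`: 800 solvent molecules (29.5 Å
box, ~2400 atoms), rigid-H protocol at 2 fs, 12 ps equilibration, 8 ps
pre-phase, T_rxn = 40 ps with 2-ps updates (sigmoidal), 10 ps post-phase;
1-ps block statistics of potential energy and temperature against the
pre-phase baseline.  `benchmarks.run_morph_outcome_benchmark`: 150
solvent molecules, T_rxn = 20 ps, 20 ps post-phase; measures the relaxed
S–C bond length, the departure of the leaving ion and net-charge
conservation along λ.  These sizes keep each experiment within minutes on
one CPU while leaving the measured quantities stable across seeds.

The sigmoidal switching shape is the default for these experiments
because its zero initial slope avoids the hard energy injection of
switching on the leaving-group pair LJ while that atom still sits at
bonded distance; the linear shape gives the same endpoints and the same
final structures.

A scale caveat worth stating explicitly: the potential-energy transient
during the switch (the cost of the artificial "transition state", with
both bonding patterns partially engaged) is an *intensive* quantity —
roughly 300 kcal/mol for this chemistry regardless of how much solvent
surrounds it — while the total potential energy is extensive.  Expressed
as a percentage of |E_pot|, the transient therefore shrinks only as the
system grows; at 800 solvent molecules it is a few percent, an order of
magnitude larger than on production-scale solvated-protein systems where
the same absolute transient is a fraction of a percent.  The
accompanying checks — temperature pinned by the thermostat throughout,
and the block-mean potential energy returning to the pre-reaction
baseline within two standard deviations after the switch — are scale-free
and hold here.

## Analysis conventions

- Block traces: contiguous blocks, partial trailing block dropped.
- Combined chemical-shift perturbation: Δ = √(0.5·ΔδHN² + 0.07·ΔδN²),
  the standard amide ¹H/¹⁵N mapping weights.
- Secondary shifts δ_sec = δ − δ_rc; the random-coil catalogue is an
  input table and must be the same on both sides of any comparison.
- Shift agreement: Pearson r and rmsd per nucleus class (¹³C′, ¹³Cα,
  ¹³Cβ, ¹⁵N, ¹HN) plus a pooled-carbon row; classes with < 3 matched
  pairs are skipped with a warning.
- Superposition: Kabsch least squares (proper rotation); RMSF is computed
  after superposing all frames onto the first over the selection.
- Hydrogen bonds: donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 120°,
  both configurable (these criteria are a package choice; published
  occupancy percentages depend on the chosen geometry definition).
- Kinetics: pseudo-first-order least squares, half-life parameterization;
  a fit whose amplitude is negligible against the data scale is flagged
  as unidentifiable rather than reported.

## Known limitations

- No mesh electrostatics; force-shifted truncation perturbs dielectric
  screening at long range.
- Weak-coupling barostat (mean pressure only); the adiabaticity
  experiment runs at constant volume, asserting potential energy and
  temperature.
- O(N²) neighbor-list rebuilds bound practical system size to a few
  thousand atoms.
- Exactly one reactive pair per run; competing sites are out of scope.
- The morph carries no free-energy machinery: barrier heights and rate
  constants are explicitly not modelled.
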