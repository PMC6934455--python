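"""Engine physics: force/energy consistency, integrators, observables."""

import math

import numpy as np
import pytest

from conftest import make_lj_fluid, make_two_atom_bond, random_states
from morphmd.engine import (
    KB,
    EnergyModel,
    EngineConfig,
    Integrator,
    KCAL_TO_AKMA,
    OverlapError,
    apply_constraints,
    instantaneous_pressure,
    instantaneous_temperature,
    kinetic_energy,
    maxwell_boltzmann_velocities,
    minimize,
    potential_energy_forces,
    run_md,
)
from morphmd.system import SystemState
from morphmd.topology import (
    AngleTerm,
    AtomRecord,
    BondTerm,
    DihedralTerm,
    DistanceRestraint,
    Topology,
)


def finite_difference_forces(model, state, h=1e-5):
    pos = state.positions
    num = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            for sign in (1, -1):
                trial = pos.copy()
                trial[i, d] += sign * h
                e = model.energy_forces(
                    SystemState(trial, box=state.box)
                )[0].total
                num[i, d] -= sign * e
    return num / (2 * h)


def assert_forces_consistent(topology, states, cutoff=None, rel=1e-4):
    model = EnergyModel(topology, cutoff=cutoff)
    for state in states:
        _, analytic, _ = model.energy_forces(state)
        numeric = finite_difference_forces(model, state)
        scale = max(1.0, float(np.max(np.abs(numeric))))
        assert np.max(np.abs(analytic - numeric)) / scale < rel


class TestForces:
    def test_bond_at_minimum_is_zero(self):
        topo, state = make_two_atom_bond(r=1.8)
        br, forces = potential_energy_forces(topo, state, cutoff=None)
        assert br.bond == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(forces, 0.0, atol=1e-12)

    def test_bond_energy_hand_value(self):
        # k (r - r0)^2 = 300 * 0.1^2 = 3 kcal/mol
        topo, state = make_two_atom_bond(r=1.9)
        br, _ = potential_energy_forces(topo, state, cutoff=None)
        assert br.bond == pytest.approx(3.0, rel=1e-12)
        assert br.total == pytest.approx(
            br.bond + br.angle + br.dihedral + br.vdw + br.coulomb + br.restraint
        )

    @pytest.mark.parametrize("term", ["bond", "angle", "dihedral", "restraint", "flat"])
    def test_each_term_matches_finite_differences(self, term):
        atoms = [AtomRecord(i, f"A{i}", 0, "M", 12.0, 0.0) for i in range(4)]
        topo = Topology(atoms=atoms)
        topo.nonbonded_overrides = {
            (i, j): (0.0, 0.0) for i in range(4) for j in range(i + 1, 4)
        }
        if term == "bond":
            topo.bonds = [BondTerm(0, 1, 310.0, 1.5)]
            topo.nonbonded_overrides.pop((0, 1))  # exclusion comes from the bond
        elif term == "angle":
            topo.angles = [AngleTerm(0, 1, 2, 55.0, 1.9)]
        elif term == "dihedral":
            topo.dihedrals = [DihedralTerm(0, 1, 2, 3, 2.5, 3, 0.6)]
        elif term == "restraint":
            topo.restraints = [DistanceRestraint(0, 3, 25.0, 2.5, 0.6)]
        else:
            topo.restraints = [DistanceRestraint(0, 3, 25.0, 1.5, 1.0, flat_bottom=True)]
        rng = np.random.default_rng(5)
        states = [
            SystemState(rng.normal(scale=1.6, size=(4, 3))) for _ in range(8)
        ]
        assert_forces_consistent(topo, states, cutoff=None)

    def test_nonbonded_and_scaled14_match_finite_differences(self):
        # 4-atom chain gives one scaled 1-4 pair; extra charges/LJ everywhere
        atoms = [
            AtomRecord(i, f"A{i}", 0, "M", 12.0, (-1) ** i * 0.3, 0.12, 1.8)
            for i in range(5)
        ]
        topo = Topology(atoms=atoms)
        topo.bonds = [BondTerm(i, i + 1, 300.0, 1.5) for i in range(3)]
        rng = np.random.default_rng(6)
        base = np.array([[i * 1.5, 0.0, 0.0] for i in range(5)])
        box = np.full(3, 12.0)
        states = [
            SystemState(base + rng.normal(scale=0.3, size=base.shape) + 4.0, box=box)
            for _ in range(8)
        ]
        assert_forces_consistent(topo, states, cutoff=5.0)

    def test_dry_fixture_forces_match_finite_differences(self, dry_fixture):
        """Full gas-phase model system: every implemented term at once."""
        from morphmd.fixtures import _solute_positions

        base = _solute_positions(np.full(3, 10.0))
        states = random_states(base, 10, 0.05, seed=9)
        assert_forces_consistent(dry_fixture.topo_reactant, states, cutoff=None)

    def test_overlap_raises(self):
        atoms = [AtomRecord(i, "A", 0, "M", 12.0, 0.1, 0.1, 1.8) for i in range(2)]
        topo = Topology(atoms=atoms)
        state = SystemState(np.zeros((2, 3)))
        with pytest.raises(OverlapError):
            potential_energy_forces(topo, state, cutoff=None)


class TestMinimize:
    def test_stretched_bond_relaxes_to_equilibrium(self):
        topo, state = make_two_atom_bond(r=2.5)
        out = minimize(topo, state, max_steps=500, cutoff=None)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert abs(r - 1.8) < 1e-3

    def test_already_minimal_unchanged(self):
        topo, state = make_two_atom_bond(r=1.8)
        out = minimize(topo, state, max_steps=100, cutoff=None)
        assert np.max(np.abs(out.positions - state.positions)) < 1e-6

    def test_fixture_energy_nonincreasing(self, small_fixture):
        model = EnergyModel(small_fixture.topo_reactant, cutoff=6.0)
        e0 = model.energy_forces(small_fixture.state)[0].total
        out = minimize(
            small_fixture.topo_reactant, small_fixture.state,
            max_steps=600, cutoff=6.0, posres_k=200.0, posres_steps=500,
        )
        e1 = model.energy_forces(out)[0].total
        assert e1 <= e0


class TestIntegration:
    def test_nve_harmonic_oscillator_energy_drift(self):
        """gamma = 0 velocity Verlet conserves the oscillator energy.

        The spring is chosen so that the velocity-Verlet shadow-energy
        oscillation (omega dt)^2 E / 8 sits below the 1e-5 bound; any
        systematic drift would breach it immediately.
        """
        topo, state = make_two_atom_bond(k=1.0, r0=1.8, r=2.3, mass=16.0)
        cfg = EngineConfig(timestep=0.0005, cutoff=None, friction=0.0)
        integ = Integrator(topo, cfg, np.random.default_rng(0))
        e0 = integ.model.energy_forces(state)[0].total + kinetic_energy(state, topo)
        worst = 0.0
        for k in range(10_000):
            integ.step(state)
            if k % 100 == 99:
                e = integ.breakdown.total + kinetic_energy(state, topo)
                worst = max(worst, abs(e - e0) / abs(e0))
        assert worst <= 1e-5

    def test_nve_momentum_conservation(self, dry_fixture):
        topo = dry_fixture.topo_reactant
        state = dry_fixture.state.copy()
        state.box = None
        rng = np.random.default_rng(3)
        state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng, remove_com=False)
        m = topo.masses()[:, None]
        p0 = (m * state.velocities).sum(axis=0)
        cfg = EngineConfig(timestep=0.0005, cutoff=None, friction=0.0)
        integ = Integrator(topo, cfg, rng)
        for _ in range(2000):
            integ.step(state)
        p1 = (m * state.velocities).sum(axis=0)
        scale = max(1.0, float(np.max(np.abs(p0))), float(np.sum(np.abs(m * state.velocities))))
        assert np.max(np.abs(p1 - p0)) / scale < 1e-8

    def test_langevin_thermostat_mean_temperature(self):
        """LJ fluid at 293 K, gamma = 2 ps^-1: time-mean T within 3%."""
        topo, state = make_lj_fluid()
        rng = np.random.default_rng(11)
        state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng)
        cfg = EngineConfig(timestep=0.002, cutoff=5.0, friction=2.0, temperature=293.0)
        res = run_md(topo, state, cfg, 50.0, rng=rng, save_interval=0.1)
        mean_t = res.log["temperature"].iloc[50:].mean()
        assert abs(mean_t - 293.0) / 293.0 < 0.03

    def test_thermostat_variance_consistent_with_equipartition(self):
        """Var(T) for N_dof degrees of freedom is 2 T^2 / N_dof (within x2)."""
        topo, state = make_lj_fluid()
        rng = np.random.default_rng(12)
        state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng)
        cfg = EngineConfig(timestep=0.002, cutoff=5.0, friction=2.0, temperature=293.0)
        res = run_md(topo, state, cfg, 40.0, rng=rng, save_interval=0.05)
        t = res.log["temperature"].iloc[100:]
        ndof = 3 * topo.n_atoms - 3
        expected_var = 2.0 * 293.0**2 / ndof
        assert expected_var / 2 < t.var() < expected_var * 2

    def test_berendsen_barostat_mean_pressure(self):
        """Weak-coupling barostat drives the LJ fluid's mean pressure toward
        the target (asserted on the long-run mean only)."""
        topo, state = make_lj_fluid(n_side=5, box_edge=11.0)
        rng = np.random.default_rng(13)
        state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng)
        cfg = EngineConfig(
            timestep=0.002, cutoff=5.0, friction=2.0, temperature=293.0,
            barostat=True, pressure=500.0, tau_p=0.5,
        )
        res = run_md(topo, state, cfg, 60.0, rng=rng, save_interval=0.1)
        mean_p = res.log["pressure"].iloc[200:].mean()
        assert abs(mean_p - 500.0) <= 0.2 * 500.0

    def test_identical_seed_identical_trajectory(self, small_fixture, small_config,
                                                 equilibrated_small):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            res = run_md(
                small_fixture.topo_reactant, equilibrated_small, small_config,
                0.2, rng=rng, save_interval=0.1,
            )
            runs.append(res.final_state.positions)
        assert np.array_equal(runs[0], runs[1])


class TestObservables:
    def test_zero_velocities_zero_temperature(self, dry_fixture):
        state = dry_fixture.state.copy()
        assert instantaneous_temperature(state, dry_fixture.topo_reactant) == 0.0

    def test_constructed_kinetic_energy_gives_exact_temperature(self):
        topo, state = make_two_atom_bond()
        ndof = 3 * 2 - 3
        ke = 0.5 * ndof * KB * 300.0
        # put all kinetic energy in atom 0 along x
        v = math.sqrt(2 * ke * KCAL_TO_AKMA / topo.atoms[0].mass)
        state.velocities[0, 0] = v
        assert instantaneous_temperature(state, topo) == pytest.approx(300.0, rel=1e-12)

    def test_maxwell_boltzmann_sampling_mean(self):
        topo = Topology(
            atoms=[AtomRecord(i, "A", i, "M", 16.0, 0.0) for i in range(1000)]
        )
        state = SystemState(np.zeros((1000, 3)))
        rng = np.random.default_rng(21)
        temps = []
        for _ in range(100):
            state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng)
            temps.append(instantaneous_temperature(state, topo))
        assert abs(np.mean(temps) - 293.0) / 293.0 < 0.02

    def test_ideal_gas_pressure(self):
        topo, state = make_lj_fluid(n_side=3, box_edge=30.0)
        for a in topo.atoms:
            a.lj_epsilon = 0.0  # non-interacting
        rng = np.random.default_rng(8)
        state.velocities = maxwell_boltzmann_velocities(topo, 293.0, rng)
        t = instantaneous_temperature(state, topo)
        expected = (
            topo.n_atoms * KB * t / state.volume * 69476.95
        )
        p = instantaneous_pressure(state, topo, virial=0.0)
        assert p == pytest.approx(expected, rel=1e-6)

    def test_lj_pair_at_minimum_contributes_no_virial(self):
        atoms = [AtomRecord(i, "A", i, "M", 16.0, 0.0, 0.2, 1.9) for i in range(2)]
        topo = Topology(atoms=atoms)
        state = SystemState(
            np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]]), box=np.full(3, 30.0)
        )
        model = EnergyModel(topo, cutoff=10.0, coulomb_shifted=False)
        _, forces, virial = model.energy_forces(state)
        assert np.allclose(forces, 0.0, atol=1e-10)
        assert virial == pytest.approx(0.0, abs=1e-10)

    def test_virial_matches_bruteforce_pair_loop(self):
        """Independent O(N^2) pairwise virial summation oracle."""
        topo, state = make_lj_fluid(n_side=3, box_edge=9.0)
        rng = np.random.default_rng(4)
        state.positions += rng.normal(scale=0.2, size=state.positions.shape)
        cutoff = 4.0
        model = EnergyModel(topo, cutoff=cutoff, coulomb_shifted=False)
        _, _, virial = model.energy_forces(state)
        w = 0.0
        box = state.box
        for i in range(topo.n_atoms):
            for j in range(i + 1, topo.n_atoms):
                d = state.positions[i] - state.positions[j]
                d -= box * np.rint(d / box)
                r = np.linalg.norm(d)
                if r >= cutoff:
                    continue
                eps = 0.1521
                rm = 2 * 1.77
                sr6 = (rm / r) ** 6
                f = 12.0 * eps * (sr6**2 - sr6) / r  # -dE/dr
                w += f * r
        assert virial == pytest.approx(w, rel=1e-10)


class TestConstraints:
    def _chain(self):
        atoms = [AtomRecord(i, "A", 0, "M", 12.0, 0.0) for i in range(4)]
        bonds = [BondTerm(i, i + 1, 300.0, 1.5, constrained=True) for i in range(3)]
        return Topology(atoms=atoms, bonds=bonds)

    def test_perturbed_bond_restored(self):
        topo, state = make_two_atom_bond(r=1.8 * 1.05)
        topo.bonds[0].constrained = True
        out = apply_constraints(topo, state, tolerance=1e-8)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert abs(r - 1.8) / 1.8 < 1e-8

    def test_satisfied_constraints_unchanged(self):
        topo, state = make_two_atom_bond(r=1.8)
        topo.bonds[0].constrained = True
        out = apply_constraints(topo, state)
        assert np.array_equal(out.positions, state.positions)

    def test_three_bond_chain_converges(self):
        topo = self._chain()
        pos = np.array([[0, 0, 0], [1.62, 0, 0], [3.1, 0.3, 0], [4.8, 0.1, 0.2]], float)
        state = SystemState(pos)
        out = apply_constraints(topo, state, tolerance=1e-8)
        for b in topo.bonds:
            r = np.linalg.norm(out.positions[b.j] - out.positions[b.i])
            assert abs(r - 1.5) / 1.5 < 1e-8

    def test_velocity_components_removed(self):
        topo, state = make_two_atom_bond(r=1.8)
        topo.bonds[0].constrained = True
        state.velocities = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        out = apply_constraints(topo, state)
        d = out.positions[1] - out.positions[0]
        vrel = (out.velocities[0] - out.velocities[1]) @ d
        assert abs(vrel) < 1e-6
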