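import math

import numpy as np
import pytest

from morphmd.engine import EngineConfig
from morphmd.fixtures import FixtureSpec, build_sn2_fixture, equilibrate
from morphmd.system import SystemState
from morphmd.topology import AtomRecord, BondTerm, Topology


@pytest.fixture(scope="session")
def dry_fixture():
    """Unsolvated S_N2 model system (15 atoms, gas phase)."""
    return build_sn2_fixture(FixtureSpec(solvent_count=0, box_edge=20.0, seed=7))


@pytest.fixture(scope="session")
def small_fixture():
    """Solvated model system small enough for per-test dynamics."""
    return build_sn2_fixture(
        FixtureSpec(solvent_count=64, box_edge=14.0, tether=True, seed=7)
    )


@pytest.fixture(scope="session")
def protocol_fixture():
    """Small solvated system with the proximity tether enabled, for
    exercising the full protocol machinery."""
    return build_sn2_fixture(
        FixtureSpec(solvent_count=64, box_edge=14.0, tether=True, seed=7)
    )


@pytest.fixture(scope="session")
def equilibrated_protocol(protocol_fixture, small_config):
    rng = np.random.default_rng(7)
    return equilibrate(protocol_fixture, small_config, duration=3.0, rng=rng)


@pytest.fixture(scope="session")
def small_config():
    return EngineConfig(cutoff=6.0, seed=7)


@pytest.fixture(scope="session")
def equilibrated_small(small_fixture, small_config):
    """Minimized + 3-ps-thermostatted state of the small fixture."""
    rng = np.random.default_rng(7)
    return equilibrate(small_fixture, small_config, duration=3.0, rng=rng)


def make_lj_fluid(n_side=5, box_edge=12.0, eps=0.1521, rmin_half=1.77, mass=16.0):
    """Simple-cubic LJ fluid (no charges) for thermostat/barostat checks."""
    n = n_side**3
    topo = Topology(title="lj fluid")
    for i in range(n):
        topo.atoms.append(AtomRecord(i, "LJ", i, "FLU", mass, 0.0, eps, rmin_half))
    spacing = box_edge / n_side
    pos = np.zeros((n, 3))
    k = 0
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                pos[k] = (np.array([ix, iy, iz]) + 0.5) * spacing
                k += 1
    state = SystemState(pos, box=np.full(3, box_edge))
    return topo, state


def make_two_atom_bond(k=300.0, r0=1.8, r=1.8, mass=12.0):
    topo = Topology(
        atoms=[
            AtomRecord(0, "A", 0, "MOL", mass, 0.0, 0.0, 0.0),
            AtomRecord(1, "B", 0, "MOL", mass, 0.0, 0.0, 0.0),
        ],
        bonds=[BondTerm(0, 1, k, r0)],
    )
    state = SystemState(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    return topo, state


def random_states(base_positions, n, scale, seed, box=None):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pos = base_positions + rng.normal(scale=scale, size=base_positions.shape)
        out.append(SystemState(pos, box=box))
    return out
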