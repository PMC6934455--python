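"""Molecular topology data model.

A :class:`Topology` is an editable, in-memory description of one chemical
state of the system: atoms (with masses, charges and Lennard-Jones
parameters), harmonic bond and angle terms, cosine dihedral terms, and
distance restraints.  The reactive-morphing protocol keeps *two* such
topologies loaded at once (reactant and product) and interpolates between
them, so the container is deliberately plain and cheap to copy.

Units and conventions
---------------------
* lengths in Å, angles stored in radians, masses in amu, charges in
  elementary charge units, energies in kcal/mol
* bond/angle energy ``k (x - x0)^2`` (the force constant absorbs the 1/2)
* dihedral energy ``(V_n/2) (1 + cos(n phi - gamma))``
* 1-2 and 1-3 nonbonded pairs are excluded; 1-4 pairs are scaled by the
  stored multiplicative factors (default 1/1.2 electrostatic, 1/2 vdW)
* atom indices are 0-based everywhere inside the package
"""

from __future__ import annotations

import copy
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "DistanceRestraint",
    "Topology",
    "TopologyError",
    "ValidationReport",
    "build_exclusions",
    "validate_topology",
    "nonbonded_scheme",
    "KB",
    "COULOMB_CONSTANT",
]

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041
#: Coulomb prefactor, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637


class TopologyError(ValueError):
    """Raised for malformed topologies (duplicate bonds, bad indices...)."""


@dataclass
class AtomRecord:
    """One atom: identity plus per-atom force-field parameters.

    ``lj_rmin_half`` is half the position of the LJ minimum for the
    homo-pair; pair parameters combine as ``rmin_ij = rh_i + rh_j`` and
    ``eps_ij = sqrt(eps_i eps_j)`` (Lorentz-Berthelot in rmin form).
    """

    index: int
    name: str
    residue_index: int
    residue_name: str
    mass: float
    charge: float
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0


@dataclass
class BondTerm:
    """Harmonic bond, E = k (r - r0)^2.  ``constrained`` flags the bond for
    the iterative length-constraint pass (SHAKE-style) when the engine is
    run with constraints enabled."""

    i: int
    j: int
    force_constant: float  # kcal/mol/Å^2
    equilibrium: float  # Å
    constrained: bool = False

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class AngleTerm:
    """Harmonic angle, E = k (theta - theta0)^2, theta0 in radians."""

    i: int
    j: int
    k: int
    force_constant: float  # kcal/mol/rad^2
    equilibrium: float  # radians, in (0, pi]

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k) if self.i < self.k else (self.k, self.j, self.i)


@dataclass
class DihedralTerm:
    """Cosine dihedral, E = (V_n/2)(1 + cos(n phi - gamma))."""

    i: int
    j: int
    k: int
    l: int
    barrier_half: float  # V_n/2, kcal/mol
    periodicity: int
    phase: float = 0.0  # gamma, radians

    @property
    def key(self) -> tuple[int, int, int, int, int]:
        quad = (self.i, self.j, self.k, self.l)
        if quad[::-1] < quad:
            quad = quad[::-1]
        return (*quad, self.periodicity)


@dataclass
class DistanceRestraint:
    """Weight-scaled harmonic distance restraint, E = w k (d - d0)^2.

    With ``flat_bottom=True`` only separations beyond the target are
    penalized (a one-sided tether), E = w k max(0, d - d0)^2.
    """

    i: int
    j: int
    force_constant: float  # kcal/mol/Å^2
    target: float  # Å
    weight: float = 1.0
    flat_bottom: bool = False


@dataclass
class Topology:
    """One chemical state: atoms, bonded terms, restraints, scaling rules.

    ``nonbonded_overrides`` maps an ordered atom pair ``(i, j)`` (i < j) to
    a pair of multiplicative factors ``(elec_scale, vdw_scale)`` that
    replace whatever the bond graph would dictate for that pair.  Endpoint
    topologies normally leave it empty; the morphing machinery uses it to
    crossfade pairs whose exclusion status differs between reactant and
    product.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    restraints: list[DistanceRestraint] = field(default_factory=list)
    scale14_elec: float = 1.0 / 1.2
    scale14_vdw: float = 0.5
    nonbonded_overrides: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )
    title: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def copy(self) -> "Topology":
        return copy.deepcopy(self)


def _bond_adjacency(topology: Topology) -> list[set[int]]:
    n = topology.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    seen = set()
    for b in topology.bonds:
        if b.i == b.j:
            raise TopologyError(f"bond joins atom {b.i} to itself")
        if not (0 <= b.i < n and 0 <= b.j < n):
            raise TopologyError(f"bond ({b.i}, {b.j}) references atom out of range")
        if b.key in seen:
            raise TopologyError(f"duplicate bond {b.key}")
        seen.add(b.key)
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    return adj


def build_exclusions(
    topology: Topology,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Derive nonbonded bookkeeping sets from the bond graph.

    Returns ``(excluded, scaled_14)``: a pair ``(i, j)`` (i < j) is excluded
    when the shortest bond path between the atoms has length 1 or 2, and is
    1-4 scaled when the shortest path length is exactly 3.  The two sets are
    disjoint by construction.
    """
    adj = _bond_adjacency(topology)
    excluded: set[tuple[int, int]] = set()
    scaled: set[tuple[int, int]] = set()
    for start in range(topology.n_atoms):
        # breadth-first search truncated at depth 3
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if dist[u] >= 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v, d in dist.items():
            if v <= start:
                continue
            if d in (1, 2):
                excluded.add((start, v))
            elif d == 3:
                scaled.add((start, v))
    return frozenset(excluded), frozenset(scaled)


def nonbonded_scheme(topology: Topology) -> dict[tuple[int, int], tuple[float, float]]:
    """Map each non-default pair to its ``(elec_scale, vdw_scale)`` factors.

    Pairs absent from the map interact at full strength.  Derived from the
    bond graph (exclusions -> (0, 0); 1-4 -> the topology's 1-4 factors),
    then patched with ``nonbonded_overrides``.
    """
    excluded, scaled = build_exclusions(topology)
    scheme: dict[tuple[int, int], tuple[float, float]] = {}
    for p in excluded:
        scheme[p] = (0.0, 0.0)
    for p in scaled:
        scheme[p] = (topology.scale14_elec, topology.scale14_vdw)
    for p, s in topology.nonbonded_overrides.items():
        p = (p[0], p[1]) if p[0] < p[1] else (p[1], p[0])
        if s == (1.0, 1.0):
            scheme.pop(p, None)
        else:
            scheme[p] = (float(s[0]), float(s[1]))
    return scheme


@dataclass
class ValidationReport:
    violations: list[str]
    net_charge: float

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_topology(topology: Topology) -> ValidationReport:
    """Collect structural violations; reports rather than raises.

    Checks index ranges, duplicate atom indices, positive masses, finite
    parameters, angle equilibria in (0, pi], and restraint weights in
    [0, 1]; also reports the net charge (informational, not a violation).
    """
    v: list[str] = []
    n = topology.n_atoms
    seen_idx = set()
    for a in topology.atoms:
        if a.index in seen_idx:
            v.append(f"atom index {a.index} duplicated")
        seen_idx.add(a.index)
        if not (a.mass > 0):
            v.append(f"atom {a.index} ({a.name}): nonpositive mass {a.mass}")
        for label, value in (
            ("charge", a.charge),
            ("lj_epsilon", a.lj_epsilon),
            ("lj_rmin_half", a.lj_rmin_half),
        ):
            if not math.isfinite(value):
                v.append(f"atom {a.index} ({a.name}): non-finite {label}")
        if a.lj_epsilon < 0 or a.lj_rmin_half < 0:
            v.append(f"atom {a.index} ({a.name}): negative LJ parameter")

    def _check_indices(kind, term, idx):
        for i in idx:
            if not (0 <= i < n):
                v.append(f"{kind} {idx}: index {i} out of range (n_atoms={n})")
        if len(set(idx)) != len(idx):
            v.append(f"{kind} {idx}: repeated atom index")

    seen_bonds = set()
    for b in topology.bonds:
        _check_indices("bond", b, (b.i, b.j))
        if b.key in seen_bonds:
            v.append(f"duplicate bond {b.key}")
        seen_bonds.add(b.key)
        if b.force_constant < 0 or not math.isfinite(b.force_constant):
            v.append(f"bond {b.key}: bad force constant {b.force_constant}")
        if not math.isfinite(b.equilibrium) or b.equilibrium <= 0:
            v.append(f"bond {b.key}: bad equilibrium {b.equilibrium}")
    for a in topology.angles:
        _check_indices("angle", a, (a.i, a.j, a.k))
        if a.force_constant < 0 or not math.isfinite(a.force_constant):
            v.append(f"angle {a.key}: bad force constant {a.force_constant}")
        if not (0.0 < a.equilibrium <= math.pi + 1e-12):
            v.append(f"angle {a.key}: equilibrium {a.equilibrium} outside (0, pi]")
    for d in topology.dihedrals:
        _check_indices("dihedral", d, (d.i, d.j, d.k, d.l))
        if not math.isfinite(d.barrier_half):
            v.append(f"dihedral {d.key}: non-finite barrier")
        if d.periodicity < 1:
            v.append(f"dihedral {d.key}: periodicity {d.periodicity} < 1")
    for r in topology.restraints:
        _check_indices("restraint", r, (r.i, r.j))
        if r.force_constant < 0:
            v.append(f"restraint ({r.i},{r.j}): negative force constant")
        if not (0.0 <= r.weight <= 1.0):
            v.append(f"restraint ({r.i},{r.j}): weight {r.weight} outside [0,1]")
    return ValidationReport(v, topology.net_charge())
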