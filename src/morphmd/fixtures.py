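"""Deterministic model-system generator for the reactive-morphing protocol.

The fixture emulates, at desk scale, an S_N2 thioether conjugation: a
thiolate-like nucleophile fragment (net charge −1) attacks the
electrophilic carbon of a chloroacetamide-like substrate, expelling the
leaving atom L as a free anion.  Both endpoint topologies (noncovalent
reactant, covalent product), the morph map between them, a neutralizing
counterion and a box of flexible 3-site water-like solvent are generated
from a single seed, so every module of the package is exercisable with no
external data.

The force-field numbers here are plausible textbook magnitudes for the
atom types involved (bond k ≈ 200–600 kcal/mol/Å², LJ ε ≈ 0.02–0.27
kcal/mol, water-like charges ±0.4/−0.8); they are placeholders standing in
for a real parameterization, chosen for stability rather than chemical
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .engine import (
    EngineConfig,
    maxwell_boltzmann_velocities,
    minimize,
    run_md,
)
from .morph import MorphMap, build_morph_map
from .system import SystemState
from .topology import (
    AngleTerm,
    AtomRecord,
    BondTerm,
    DihedralTerm,
    DistanceRestraint,
    Topology,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "build_sn2_fixture",
    "build_distance_series",
    "equilibrate",
    "SOLUTE_ATOMS",
    "REACTIVE_PAIR",
]

_DEG = math.pi / 180.0

# solute atom order (indices are fixed by construction)
SOLUTE_ATOMS = (
    "CB", "HB1", "HB2", "HB3", "SG",  # thiolate-like nucleophile
    "CT", "HT1", "HT2", "L", "CE", "OE", "NE", "HN1", "HN2",  # substrate
    "NA",  # counterion
)
I = {name: k for k, name in enumerate(SOLUTE_ATOMS)}
#: (nucleophile sulfur, electrophilic carbon) — the distance the trigger watches
REACTIVE_PAIR = (I["SG"], I["CT"])

# per-atom-type LJ and mass tables (eps kcal/mol, rmin/2 Å, mass amu)
_TYPES = {
    "C": (0.1094, 1.908, 12.011),
    "HC": (0.0157, 1.387, 1.008),
    "HN": (0.0157, 0.600, 1.008),
    "S": (0.25, 2.0, 32.06),
    "CL": (0.265, 2.22, 35.45),
    "O": (0.21, 1.6612, 15.999),
    "N": (0.17, 1.824, 14.007),
    "NA+": (0.0874, 1.369, 22.99),
    "OW": (0.1521, 1.7683, 15.999),
    "HW": (0.046, 0.2245, 1.008),
}

_ATOM_TYPE = {
    "CB": "C", "HB1": "HC", "HB2": "HC", "HB3": "HC", "SG": "S",
    "CT": "C", "HT1": "HC", "HT2": "HC", "L": "CL",
    "CE": "C", "OE": "O", "NE": "N", "HN1": "HN", "HN2": "HN",
    "NA": "NA+",
}

# partial charges per endpoint; both states sum to zero with the counterion.
# the electrophilic carbon CT is partially positive (bonded to the leaving
# halide and the carbonyl), so the thiolate approach is Coulomb-favorable.
_Q_REACTANT = {
    "CB": -0.20, "HB1": 0.03, "HB2": 0.03, "HB3": 0.03, "SG": -0.89,
    "CT": 0.15, "HT1": 0.06, "HT2": 0.06, "L": -0.25,
    "CE": 0.50, "OE": -0.55, "NE": -0.82, "HN1": 0.425, "HN2": 0.425,
    "NA": 1.0,
}
_Q_PRODUCT = {
    **_Q_REACTANT,
    "CB": -0.15, "SG": -0.30, "CT": 0.18, "HT1": 0.10, "HT2": 0.10, "L": -1.0,
}

# bond table: (i, j, k kcal/mol/Å², r0 Å); shared bonds plus per-endpoint
# extras.  X-H bonds are flagged constrainable so the engine can run the
# conventional rigid-H protocol (SHAKE + 2 fs step) when asked to.
_BONDS_COMMON = [
    ("CB", "HB1", 340.0, 1.09), ("CB", "HB2", 340.0, 1.09), ("CB", "HB3", 340.0, 1.09),
    ("CB", "SG", 227.0, 1.81),
    ("CT", "HT1", 340.0, 1.09), ("CT", "HT2", 340.0, 1.09),
    ("CT", "CE", 310.0, 1.52),
    ("CE", "OE", 570.0, 1.23), ("CE", "NE", 490.0, 1.34),
    ("NE", "HN1", 434.0, 1.01), ("NE", "HN2", 434.0, 1.01),
]
_H_BOND_NAMES = {
    ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3"),
    ("CT", "HT1"), ("CT", "HT2"), ("NE", "HN1"), ("NE", "HN2"),
}
_BOND_REACTANT_ONLY = [("CT", "L", 227.0, 1.79)]
_BOND_PRODUCT_ONLY = [("SG", "CT", 227.0, 1.81)]

# angle parameters by central atom (k kcal/mol/rad², theta0 deg)
_ANGLE_BY_CENTER = {"S": (62.0, 98.9), "N": (50.0, 120.0)}
_SP2_CENTERS = {"CE"}

_WATER_BOND = (450.0, 0.9572)
_WATER_ANGLE = (55.0, 104.52)
_WATER_Q = {"OW": -0.8, "HW": 0.4}


@dataclass
class FixtureSpec:
    """Knobs of the generated system.

    ``tether`` adds a flat-bottom harmonic restraint between the reactive
    atoms, standing in for the noncovalent-complex preorganization that
    holds nucleophile and substrate together; enable it for protocol runs
    so the trigger fires within desk-scale watch times.  The flat bottom
    defaults to 3.2 Å, just inside the capture radius: with any looser
    tether, sub-capture approaches against the S/C Lennard-Jones wall
    (contact distance ~3.9 Å) plus the desolvation penalty remain rare
    activated events with waiting times far beyond desk scale, defeating
    the tether's purpose.  The stochastic acceptance gate, not the tether,
    then controls when the reaction starts.
    """

    solvent_model: str = "water3"  # "water3" or "lj"
    solvent_count: int = 200
    box_edge: float = 20.0
    tether: bool = False
    tether_target: float = 3.2  # Å, flat-bottom onset
    tether_k: float = 10.0  # kcal/mol/Å²
    seed: int = 2026

    def __post_init__(self) -> None:
        if self.solvent_model not in ("water3", "lj"):
            raise ValueError("solvent_model must be 'water3' or 'lj'")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")


@dataclass
class Fixture:
    spec: FixtureSpec
    topo_reactant: Topology
    topo_product: Topology
    morph: MorphMap
    state: SystemState
    reactive_pair: tuple[int, int] = REACTIVE_PAIR
    indices: dict[str, int] = field(default_factory=lambda: dict(I))


def _angles_from_bonds(bonds, names) -> list[AngleTerm]:
    adj: dict[int, set[int]] = {}
    for b in bonds:
        adj.setdefault(b.i, set()).add(b.j)
        adj.setdefault(b.j, set()).add(b.i)
    out = []
    for j, nbrs in sorted(adj.items()):
        ns = sorted(nbrs)
        for a in range(len(ns)):
            for c in range(a + 1, len(ns)):
                center = names[j]
                ttype = _ATOM_TYPE.get(center, "C")
                if ttype in _ANGLE_BY_CENTER:
                    k, t0 = _ANGLE_BY_CENTER[ttype]
                elif center in _SP2_CENTERS:
                    k, t0 = 70.0, 120.0
                else:
                    k, t0 = 50.0, 109.47
                out.append(AngleTerm(ns[a], j, ns[c], k, t0 * _DEG))
    return out


def _dihedrals_from_bonds(bonds, names) -> list[DihedralTerm]:
    adj: dict[int, set[int]] = {}
    for b in bonds:
        adj.setdefault(b.i, set()).add(b.j)
        adj.setdefault(b.j, set()).add(b.i)
    out = []
    for b in bonds:
        j, k = b.i, b.j
        for i in sorted(adj.get(j, ()) - {k}):
            for l in sorted(adj.get(k, ()) - {j}):
                if i == l:
                    continue
                if {names[j], names[k]} == {"CE", "NE"}:
                    out.append(DihedralTerm(i, j, k, l, 2.0, 2, math.pi))
                else:
                    out.append(DihedralTerm(i, j, k, l, 0.15, 3, 0.0))
    return out


def _solute_positions(center: np.ndarray) -> np.ndarray:
    """Chemically sensible starting geometry: nucleophile poised ~4 Å from
    the electrophilic carbon, opposite the leaving atom."""
    p = np.zeros((len(SOLUTE_ATOMS), 3))
    ct = center

    def unit(v):
        v = np.asarray(v, dtype=float)
        return v / np.linalg.norm(v)

    p[I["CT"]] = ct
    p[I["L"]] = ct + 1.79 * unit([-1.0, 0.0, 0.0])
    p[I["CE"]] = ct + 1.52 * unit([0.33, 0.94, 0.0])
    p[I["HT1"]] = ct + 1.09 * unit([0.33, -0.47, 0.82])
    p[I["HT2"]] = ct + 1.09 * unit([0.33, -0.47, -0.82])
    p[I["OE"]] = p[I["CE"]] + 1.23 * unit([-0.50, 0.87, 0.0])
    p[I["NE"]] = p[I["CE"]] + 1.34 * unit([1.0, 0.55, 0.0])
    p[I["HN1"]] = p[I["NE"]] + 1.01 * unit([1.0, -0.3, 0.0])
    p[I["HN2"]] = p[I["NE"]] + 1.01 * unit([0.3, 1.0, 0.0])
    p[I["SG"]] = ct + 4.0 * unit([1.0, 0.0, 0.0])
    p[I["CB"]] = p[I["SG"]] + 1.81 * unit([0.3, -1.0, 0.0])
    cb = p[I["CB"]]
    p[I["HB1"]] = cb + 1.09 * unit([1.0, -0.4, 0.7])
    p[I["HB2"]] = cb + 1.09 * unit([-0.9, -0.5, 0.6])
    p[I["HB3"]] = cb + 1.09 * unit([0.0, -0.5, -1.0])
    p[I["NA"]] = ct + np.array([0.0, -4.5, 3.5])
    return p


def build_sn2_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate both endpoint topologies, the morph map and the initial
    solvated coordinates from ``spec`` (same seed ⇒ bit-identical output).

    Raises if the box cannot host the requested solvent count with the
    minimum lattice spacing.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    def make_topology(extra_bonds, charges, title) -> Topology:
        topo = Topology(title=title)
        for name in SOLUTE_ATOMS:
            eps, rh, mass = _TYPES[_ATOM_TYPE[name]]
            resname = {"NA": "ION"}.get(name, "NUC" if name in SOLUTE_ATOMS[:5] else "SUB")
            resid = {"NA": 2}.get(name, 0 if name in SOLUTE_ATOMS[:5] else 1)
            topo.atoms.append(
                AtomRecord(I[name], name, resid, resname, mass, charges[name], eps, rh)
            )
        for ni, nj, k, r0 in _BONDS_COMMON + extra_bonds:
            topo.bonds.append(
                BondTerm(I[ni], I[nj], k, r0, constrained=(ni, nj) in _H_BOND_NAMES)
            )
        names = list(SOLUTE_ATOMS)
        topo.angles = _angles_from_bonds(topo.bonds, names)
        topo.dihedrals = _dihedrals_from_bonds(topo.bonds, names)
        if spec.tether:
            si, ci = REACTIVE_PAIR
            topo.restraints.append(
                DistanceRestraint(
                    si, ci, spec.tether_k, spec.tether_target,
                    weight=1.0, flat_bottom=True,
                )
            )
        return topo

    topo_r = make_topology(_BOND_REACTANT_ONLY, _Q_REACTANT, "sn2 reactant")
    topo_p = make_topology(_BOND_PRODUCT_ONLY, _Q_PRODUCT, "sn2 product")

    # ---- coordinates ----------------------------------------------------
    box = np.full(3, float(spec.box_edge))
    center = box / 2.0
    solute = _solute_positions(center)
    positions = [solute]

    # grow the lattice until enough sites survive pruning around the solute,
    # without letting the spacing drop below a safe contact distance
    sites: list[np.ndarray] = []
    n_side = max(2, math.ceil(spec.solvent_count ** (1.0 / 3.0)))
    while spec.solvent_count > 0:
        spacing = spec.box_edge / n_side
        if spacing < 2.7:
            raise ValueError(
                f"box edge {spec.box_edge} Å too small for {spec.solvent_count} "
                f"solvent molecules (lattice spacing {spacing:.2f} Å < 2.7 Å)"
            )
        site_rng = np.random.default_rng(spec.seed)
        sites = []
        for ix in range(n_side):
            for iy in range(n_side):
                for iz in range(n_side):
                    site = (np.array([ix, iy, iz]) + 0.5) * spacing
                    site = site + site_rng.uniform(-0.25, 0.25, 3)
                    d = solute - site
                    d -= box * np.rint(d / box)
                    if np.min(np.sum(d * d, axis=1)) > 2.6**2:
                        sites.append(site)
        if len(sites) >= spec.solvent_count:
            break
        n_side += 1
    order = rng.permutation(len(sites))[: spec.solvent_count]

    placed_o: list[np.ndarray] = []
    kb, r0w = _WATER_BOND
    ka, t0w = _WATER_ANGLE
    half = t0w * _DEG / 2.0
    ref_h = np.array(
        [
            [r0w * math.sin(half), r0w * math.cos(half), 0.0],
            [-r0w * math.sin(half), r0w * math.cos(half), 0.0],
        ]
    )
    water_xyz = []
    for si in order:
        o = sites[si]
        if spec.solvent_model == "lj":
            water_xyz.append(o[None, :])
            continue
        for _ in range(60):
            rot = Rotation.random(random_state=rng).as_matrix()
            hpos = o + ref_h @ rot.T
            ok = True
            for prev in placed_o[-80:]:
                d = hpos - prev
                d -= box * np.rint(d / box)
                if np.min(np.sum(d * d, axis=1)) < 1.8**2:
                    ok = False
                    break
            if ok:
                break
        placed_o.append(o)
        water_xyz.append(np.vstack([o, hpos]))
    if water_xyz:
        positions.append(np.vstack(water_xyz))

    # append solvent atoms to both topologies
    for topo in (topo_r, topo_p):
        base = len(SOLUTE_ATOMS)
        for w in range(spec.solvent_count):
            if spec.solvent_model == "lj":
                eps, rh, mass = _TYPES["OW"]
                topo.atoms.append(
                    AtomRecord(base + w, "LJ", 3 + w, "SOL", mass, 0.0, eps, rh)
                )
            else:
                oi = base + 3 * w
                for off, name, ttype in ((0, "OW", "OW"), (1, "HW1", "HW"), (2, "HW2", "HW")):
                    eps, rh, mass = _TYPES[ttype]
                    topo.atoms.append(
                        AtomRecord(
                            oi + off, name, 3 + w, "WAT", mass,
                            _WATER_Q[ttype[:2]], eps, rh,
                        )
                    )
                topo.bonds.append(BondTerm(oi, oi + 1, kb, r0w, constrained=True))
                topo.bonds.append(BondTerm(oi, oi + 2, kb, r0w, constrained=True))
                topo.angles.append(AngleTerm(oi + 1, oi, oi + 2, ka, t0w * _DEG))
                # zero-k H-H distance term: with constraints enabled it makes
                # the water rigid (3-point triangle); otherwise it is inert
                hh = 2.0 * r0w * math.sin(t0w * _DEG / 2.0)
                topo.bonds.append(BondTerm(oi + 1, oi + 2, 0.0, hh, constrained=True))

    all_pos = np.vstack(positions)
    state = SystemState(all_pos, box=box)
    morph = build_morph_map(topo_r, topo_p)
    return Fixture(spec, topo_r, topo_p, morph, state)


def equilibrate(
    fixture: Fixture,
    config: EngineConfig | None = None,
    duration: float = 5.0,
    *,
    rng: np.random.Generator | None = None,
    minimize_restrained: int = 500,
    minimize_free: int = 100,
    posres_k: float = 200.0,
) -> SystemState:
    """Standard preparation: restrained + free minimization, velocity draw
    at the target temperature, then ``duration`` ps of thermostatted MD."""
    cfg = config or EngineConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    st = minimize(
        fixture.topo_reactant,
        fixture.state,
        max_steps=minimize_restrained + minimize_free,
        cutoff=cfg.cutoff,
        posres_k=posres_k,
        posres_steps=minimize_restrained,
    )
    st.velocities = maxwell_boltzmann_velocities(fixture.topo_reactant, cfg.temperature, rng)
    if cfg.constraints:
        from .engine import apply_constraints

        st = apply_constraints(fixture.topo_reactant, st, cfg.constraint_tol)
    if duration > 0:
        st = run_md(fixture.topo_reactant, st, cfg, duration, rng=rng).final_state
    return st


def build_distance_series(
    pattern: str,
    n: int,
    seed: int = 0,
    *,
    floor: float = 3.4,
    dip_index: int | None = None,
    dip_value: float = 3.0,
    start: float = 5.0,
    step_sigma: float = 0.15,
    reflect_at: float = 2.0,
) -> np.ndarray:
    """Reproducible synthetic distance series for trigger unit tests.

    Patterns: ``always-above`` (never below ``floor``), ``single-dip``
    (exactly one frame, ``dip_index``, at ``dip_value``) and
    ``random-walk`` (Gaussian increments from ``start``, reflected at
    ``reflect_at`` so distances stay physical).
    """
    rng = np.random.default_rng(seed)
    if pattern == "always-above":
        return floor + np.abs(rng.normal(0.5, 0.3, n))
    if pattern == "single-dip":
        series = floor + 0.5 + np.abs(rng.normal(0.5, 0.3, n))
        k = n // 2 if dip_index is None else dip_index
        series[k] = dip_value
        return series
    if pattern == "random-walk":
        walk = start + np.cumsum(rng.normal(0.0, step_sigma, n))
        return reflect_at + np.abs(walk - reflect_at)
    raise ValueError(f"unknown pattern {pattern!r}")
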