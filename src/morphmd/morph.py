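"""Adiabatic topology morphing: the reactant → product transformation.

The covalent-bond-forming event is modelled by loading *two* complete
topologies — the noncovalent (reactant) and covalent (product) states — and
interpolating between their parameter sets over a reaction window T_rxn.
Force constants of terms present only in the reactant are ramped down with
(1 - λ), terms present only in the product are ramped up with λ, partial
charges mix linearly, and atom pairs whose exclusion status differs between
the endpoints have their nonbonded interaction crossfaded with the same
factors.  λ advances on a piecewise-constant schedule: T_rxn is divided
into equal update intervals and the effective parameter set is regenerated
at the start of each interval, exactly reaching the product topology in the
final interval so that the post-reaction simulation continues seamlessly
under the conventional force field.

During the morph, vanishing/appearing *bonds* are carried as weight-scaled
harmonic distance restraints (the weight is the λ-factor) and
vanishing/appearing angles and dihedrals as force-constant-scaled native
terms; at the endpoints the restraints are swapped back for the native
terms, so λ = 0 and λ = 1 reproduce the endpoint topologies field for
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EngineConfig, MDResult, SimulationUnstableError, run_md
from .system import SystemState
from .topology import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    DistanceRestraint,
    Topology,
    TopologyError,
    nonbonded_scheme,
)

__all__ = [
    "SwitchSchedule",
    "PairCrossfade",
    "MorphMap",
    "build_morph_map",
    "lambda_at",
    "effective_parameters",
    "update_count",
    "run_morph",
    "MorphResult",
]


@dataclass
class SwitchSchedule:
    """λ(t) ramp over the reaction window.

    ``t_rxn`` and ``update_interval`` in ps (defaults 2000 and 10: a 2-ns
    window updated every 10 ps); ``shape`` is ``linear`` (λ = t/T) or
    ``sigmoidal`` (cubic smoothstep 3u² − 2u³, which shares the endpoints
    and has zero slope there).
    """

    t_rxn: float = 2000.0
    update_interval: float = 10.0
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.t_rxn <= 0 or self.update_interval <= 0:
            raise ValueError("t_rxn and update_interval must be positive")
        ratio = self.t_rxn / self.update_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"t_rxn ({self.t_rxn} ps) must be an integer multiple of "
                f"update_interval ({self.update_interval} ps)"
            )
        if self.shape not in ("linear", "sigmoidal"):
            raise ValueError(f"unknown schedule shape {self.shape!r}")

    @property
    def n_updates(self) -> int:
        return int(round(self.t_rxn / self.update_interval))

    def lambda_at(self, t: float) -> float:
        if not (0.0 <= t <= self.t_rxn * (1 + 1e-12)):
            raise ValueError(f"t={t} outside [0, {self.t_rxn}]")
        u = min(t / self.t_rxn, 1.0)
        if self.shape == "linear":
            return u
        return u * u * (3.0 - 2.0 * u)


def lambda_at(schedule: SwitchSchedule, t: float) -> float:
    """Scaling factor λ ∈ [0, 1] at simulated time ``t`` into the morph."""
    return schedule.lambda_at(t)


def update_count(schedule: SwitchSchedule) -> int:
    """Number of piecewise-constant parameter updates (T_rxn / interval)."""
    return schedule.n_updates


@dataclass
class PairCrossfade:
    """Nonbonded treatment of one atom pair at the two endpoints.

    ``scale_reactant``/``scale_product`` are (elec, vdw) multiplicative
    factors; ``direction`` summarizes the change (``becoming-excluded``,
    ``becoming-interacting`` or ``rescaled``).
    """

    pair: tuple[int, int]
    scale_reactant: tuple[float, float]
    scale_product: tuple[float, float]
    direction: str


@dataclass
class MorphMap:
    """Classified difference between the two endpoint topologies."""

    reactant: Topology
    product: Topology
    vanish_bonds: list[BondTerm] = field(default_factory=list)
    appear_bonds: list[BondTerm] = field(default_factory=list)
    vanish_angles: list[AngleTerm] = field(default_factory=list)
    appear_angles: list[AngleTerm] = field(default_factory=list)
    vanish_dihedrals: list[DihedralTerm] = field(default_factory=list)
    appear_dihedrals: list[DihedralTerm] = field(default_factory=list)
    q_reactant: np.ndarray = field(default_factory=lambda: np.zeros(0))
    q_product: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pair_crossfade: dict[tuple[int, int], PairCrossfade] = field(default_factory=dict)

    @property
    def unchanged_bonds(self) -> list[BondTerm]:
        keys = {b.key for b in self.vanish_bonds}
        return [b for b in self.reactant.bonds if b.key not in keys]

    @property
    def unchanged_angles(self) -> list[AngleTerm]:
        keys = {a.key for a in self.vanish_angles}
        return [a for a in self.reactant.angles if a.key not in keys]

    @property
    def unchanged_dihedrals(self) -> list[DihedralTerm]:
        keys = {d.key for d in self.vanish_dihedrals}
        return [d for d in self.reactant.dihedrals if d.key not in keys]


def _classify(reactant_terms, product_terms, params):
    """Split term lists into (vanish, appear): a term is unchanged only if
    its key and every parameter agree exactly in both topologies."""
    rmap = {t.key: t for t in reactant_terms}
    pmap = {t.key: t for t in product_terms}
    vanish, appear = [], []
    for key, t in rmap.items():
        other = pmap.get(key)
        if other is None or any(getattr(t, p) != getattr(other, p) for p in params):
            vanish.append(t)
    for key, t in pmap.items():
        other = rmap.get(key)
        if other is None or any(getattr(t, p) != getattr(other, p) for p in params):
            appear.append(t)
    return vanish, appear


def build_morph_map(
    topo_reactant: Topology,
    topo_product: Topology,
    atom_correspondence: dict[int, int] | None = None,
) -> MorphMap:
    """Derive the vanish/appear/crossfade sets from the two endpoints.

    ``atom_correspondence`` maps reactant atom index → product atom index
    and must be a bijection on the (equal-sized) atom sets; by default the
    identity.  The product topology is re-indexed into reactant numbering
    before comparison; the stored ``product`` topology is the re-indexed
    copy, so downstream code works in a single indexing.
    """
    n = topo_reactant.n_atoms
    if topo_product.n_atoms != n:
        raise TopologyError(
            f"atom counts differ ({n} vs {topo_product.n_atoms}); the morph "
            "requires equal atom sets (a leaving group persists as an ion)"
        )
    if atom_correspondence is None:
        product = topo_product.copy()
    else:
        if sorted(atom_correspondence) != list(range(n)) or sorted(
            atom_correspondence.values()
        ) != list(range(n)):
            raise TopologyError("atom correspondence is not a bijection on 0..N-1")
        inv = {v: k for k, v in atom_correspondence.items()}
        product = topo_product.copy()
        remap = lambda i: inv[i]  # noqa: E731  (product index -> reactant index)
        new_atoms = [None] * n
        for a in product.atoms:
            a.index = remap(a.index)
            new_atoms[a.index] = a
        product.atoms = new_atoms
        for b in product.bonds:
            b.i, b.j = remap(b.i), remap(b.j)
        for a in product.angles:
            a.i, a.j, a.k = remap(a.i), remap(a.j), remap(a.k)
        for d in product.dihedrals:
            d.i, d.j, d.k, d.l = remap(d.i), remap(d.j), remap(d.k), remap(d.l)
        for r in product.restraints:
            r.i, r.j = remap(r.i), remap(r.j)
        product.nonbonded_overrides = {
            tuple(sorted((remap(i), remap(j)))): s
            for (i, j), s in product.nonbonded_overrides.items()
        }

    m = MorphMap(reactant=topo_reactant, product=product)
    m.vanish_bonds, m.appear_bonds = _classify(
        topo_reactant.bonds, product.bonds, ("force_constant", "equilibrium")
    )
    m.vanish_angles, m.appear_angles = _classify(
        topo_reactant.angles, product.angles, ("force_constant", "equilibrium")
    )
    m.vanish_dihedrals, m.appear_dihedrals = _classify(
        topo_reactant.dihedrals, product.dihedrals, ("barrier_half", "phase")
    )
    m.q_reactant = topo_reactant.charges()
    m.q_product = product.charges()

    scheme_r = nonbonded_scheme(topo_reactant)
    scheme_p = nonbonded_scheme(product)
    for pair in sorted(set(scheme_r) | set(scheme_p)):
        sr = scheme_r.get(pair, (1.0, 1.0))
        sp = scheme_p.get(pair, (1.0, 1.0))
        if sr == sp:
            continue
        if sp == (0.0, 0.0):
            direction = "becoming-excluded"
        elif sr == (0.0, 0.0):
            direction = "becoming-interacting"
        else:
            direction = "rescaled"
        m.pair_crossfade[pair] = PairCrossfade(pair, sr, sp, direction)
    return m


def effective_parameters(morph: MorphMap, lam: float) -> Topology:
    """Effective topology at mixing parameter λ.

    λ = 0 and λ = 1 return copies of the endpoint topologies themselves
    (field-for-field identical); intermediate values build the blended
    system: unchanged terms intact, vanishing bonds realized as harmonic
    restraints of weight (1 − λ), appearing bonds as restraints of weight
    λ, vanishing/appearing angles and dihedrals as force-constant-scaled
    native terms, charges mixed linearly, and every pair whose nonbonded
    status differs from what the blended bond graph would dictate pinned to
    the interpolated scale factors through ``nonbonded_overrides``.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda {lam} outside [0, 1]")
    if lam == 0.0:
        return morph.reactant.copy()
    if lam == 1.0:
        return morph.product.copy()

    topo = Topology(
        scale14_elec=morph.reactant.scale14_elec,
        scale14_vdw=morph.reactant.scale14_vdw,
        title=f"morph lambda={lam:.6f}",
    )
    for a in morph.reactant.copy().atoms:
        a.charge = (1.0 - lam) * morph.q_reactant[a.index] + lam * morph.q_product[a.index]
        topo.atoms.append(a)

    topo.bonds = [BondTerm(b.i, b.j, b.force_constant, b.equilibrium, b.constrained)
                  for b in morph.unchanged_bonds]
    topo.angles = [AngleTerm(a.i, a.j, a.k, a.force_constant, a.equilibrium)
                   for a in morph.unchanged_angles]
    for a in morph.vanish_angles:
        topo.angles.append(AngleTerm(a.i, a.j, a.k, (1.0 - lam) * a.force_constant, a.equilibrium))
    for a in morph.appear_angles:
        topo.angles.append(AngleTerm(a.i, a.j, a.k, lam * a.force_constant, a.equilibrium))
    topo.dihedrals = [DihedralTerm(d.i, d.j, d.k, d.l, d.barrier_half, d.periodicity, d.phase)
                      for d in morph.unchanged_dihedrals]
    for d in morph.vanish_dihedrals:
        topo.dihedrals.append(
            DihedralTerm(d.i, d.j, d.k, d.l, (1.0 - lam) * d.barrier_half, d.periodicity, d.phase)
        )
    for d in morph.appear_dihedrals:
        topo.dihedrals.append(
            DihedralTerm(d.i, d.j, d.k, d.l, lam * d.barrier_half, d.periodicity, d.phase)
        )

    # static restraints shared by both endpoints (e.g. a tether) are kept;
    # vanish/appear bonds ride along as weight-scaled restraints
    keys_p = {(min(r.i, r.j), max(r.i, r.j), r.target) for r in morph.product.restraints}
    topo.restraints = [
        DistanceRestraint(r.i, r.j, r.force_constant, r.target, r.weight, r.flat_bottom)
        for r in morph.reactant.restraints
        if (min(r.i, r.j), max(r.i, r.j), r.target) in keys_p
    ]
    for b in morph.vanish_bonds:
        topo.restraints.append(
            DistanceRestraint(b.i, b.j, b.force_constant, b.equilibrium, weight=1.0 - lam)
        )
    for b in morph.appear_bonds:
        topo.restraints.append(
            DistanceRestraint(b.i, b.j, b.force_constant, b.equilibrium, weight=lam)
        )

    # nonbonded: pin every pair whose interpolated endpoint treatment
    # differs from what the blended bond graph alone would give
    scheme_r = nonbonded_scheme(morph.reactant)
    scheme_p = nonbonded_scheme(morph.product)
    scheme_eff = nonbonded_scheme(topo)  # derived from unchanged bonds only
    for pair in sorted(set(scheme_r) | set(scheme_p) | set(scheme_eff)):
        sr = scheme_r.get(pair, (1.0, 1.0))
        sp = scheme_p.get(pair, (1.0, 1.0))
        target = (
            (1.0 - lam) * sr[0] + lam * sp[0],
            (1.0 - lam) * sr[1] + lam * sp[1],
        )
        derived = scheme_eff.get(pair, (1.0, 1.0))
        if target != derived:
            topo.nonbonded_overrides[pair] = target
    return topo


@dataclass
class MorphResult:
    final_state: SystemState
    log: pd.DataFrame
    trajectory: MDResult | None = None
    lambdas: list[float] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)


def run_morph(
    engine_config: EngineConfig,
    morph: MorphMap,
    schedule: SwitchSchedule,
    state: SystemState,
    *,
    rng: np.random.Generator | None = None,
    save_interval: float | None = None,
) -> MorphResult:
    """Drive the adiabatic switch: advance the system through
    ``schedule.n_updates`` piecewise-constant parameter stages spanning
    exactly T_rxn of simulated time.

    Interval ``i`` (1-based) runs under ``effective_parameters(morph,
    λ(i · update_interval))``; the final interval therefore runs under the
    product topology itself, and the caller can continue conventionally
    from ``final_state``.  The log gains ``lambda`` and ``interval``
    columns.
    """
    if rng is None:
        rng = np.random.default_rng(engine_config.seed)
    state = state.copy()
    n = schedule.n_updates
    logs = []
    result = MorphResult(final_state=state, log=pd.DataFrame())
    if save_interval is None:
        save_interval = schedule.update_interval
    for i in range(1, n + 1):
        lam = schedule.lambda_at(i * schedule.update_interval)
        topo = effective_parameters(morph, lam)
        try:
            seg = run_md(
                topo,
                state,
                engine_config,
                schedule.update_interval,
                rng=rng,
                save_interval=save_interval,
            )
        except SimulationUnstableError as exc:
            err = SimulationUnstableError(
                f"morph unstable in interval {i}/{n} (lambda={lam:.4f}): {exc}; "
                "the switching window is likely too short for this system"
            )
            err.last_state = state  # last stable restart
            err.partial = result
            raise err from exc
        state = seg.final_state
        seg.log["lambda"] = lam
        seg.log["interval"] = i
        logs.append(seg.log)
        result.lambdas.extend([lam] * len(seg.times))
        result.times.extend(seg.times)
        result.frames.extend(seg.frames)
    result.final_state = state
    result.log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    return result
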