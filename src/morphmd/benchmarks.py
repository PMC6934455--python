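"""Canned end-to-end experiments on the model S_N2 system.

These functions wire the fixture generator, engine, trigger and analysis
modules into the two standard desk-scale experiments used to validate the
protocol: the adiabaticity check (does the switching perturb the
macroscopic observables?) and the morph-outcome check (does the reaction
actually produce the covalent product with an expelled leaving ion?).
They exist so that scripts and tests measure exactly the same quantities
from exactly the same study conditions.

Problem sizes are chosen for a single desk CPU: the adiabaticity run uses
800 three-site solvent molecules with a 40-ps switching window updated
every 2 ps, and the outcome run 150 solvent molecules with a 20-ps window.
Both use the conventional rigid-H protocol (bond constraints + 2-fs step)
and a sigmoidal switching shape, whose zero initial slope avoids the hard
energy injection of switching on the leaving-group nonbonded interaction
while it still sits at bonded distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import block_trace
from .engine import EngineConfig
from .fixtures import FixtureSpec, build_sn2_fixture, equilibrate
from .morph import SwitchSchedule, effective_parameters
from .trigger import ProtocolResult, ReactionConfig, pair_distance_series, run_protocol

__all__ = [
    "AdiabaticityReport",
    "MorphOutcomeReport",
    "run_adiabaticity_benchmark",
    "run_morph_outcome_benchmark",
]


@dataclass
class AdiabaticityReport:
    baseline_potential: float  # mean of pre-phase 1-ps block means, kcal/mol
    pre_block_std: float  # std of pre-phase block means, kcal/mol
    peak_deviation: float  # max |block mean - baseline| during+after morph
    peak_deviation_percent: float  # 100 * peak / |baseline|
    pre_temperature_mean: float  # K
    pre_temperature_block_std: float  # K
    peak_temperature_deviation: float  # K, during+after morph
    initiation_time: float
    result: ProtocolResult


def run_adiabaticity_benchmark(
    seed: int = 1,
    *,
    solvent_count: int = 800,
    box_edge: float = 29.5,
    t_rxn: float = 40.0,
    update_interval: float = 2.0,
    shape: str = "sigmoidal",
    equilibration: float = 12.0,
    pre_phase: float = 8.0,
    post_phase: float = 10.0,
    block_length: float = 1.0,
) -> AdiabaticityReport:
    """Run the scaled-down adiabaticity experiment and summarize how far the
    block-averaged potential energy and temperature depart from the
    pre-reaction baseline during and after the switching window."""
    rng = np.random.default_rng(seed)
    fix = build_sn2_fixture(
        FixtureSpec(
            solvent_count=solvent_count, box_edge=box_edge, tether=True,
            seed=int(rng.integers(2**31)),
        )
    )
    cfg = EngineConfig(
        timestep=0.002, cutoff=9.0, constraints=True,
        seed=int(rng.integers(2**31)),
    )
    st = equilibrate(fix, cfg, duration=equilibration, rng=rng)
    sched = SwitchSchedule(t_rxn=t_rxn, update_interval=update_interval, shape=shape)
    rcfg = ReactionConfig(
        reactive_pair=fix.reactive_pair,
        pre_phase=pre_phase,
        segment_length=2.0,
        checkpoint_interval=0.1,
        max_watch_time=60.0,
        post_phase=post_phase,
        seed=int(rng.integers(2**31)),
    )
    res = run_protocol(
        fix.topo_reactant, fix.topo_product, fix.morph, sched, rcfg, cfg, st, rng=rng
    )
    if not res.initiated:
        raise RuntimeError("adiabaticity benchmark: reaction did not initiate")
    pre = res.logs["pre"]
    after = pd.concat([res.logs["morph"], res.logs["post"]], ignore_index=True)
    bp = block_trace(pre["potential"].to_numpy(), pre["time"].to_numpy(), block_length)
    ba = block_trace(after["potential"].to_numpy(), after["time"].to_numpy(), block_length)
    baseline = float(bp.means.mean())
    peak = float(np.max(np.abs(ba.means - baseline)))
    tp = block_trace(pre["temperature"].to_numpy(), pre["time"].to_numpy(), block_length)
    ta = block_trace(after["temperature"].to_numpy(), after["time"].to_numpy(), block_length)
    return AdiabaticityReport(
        baseline_potential=baseline,
        pre_block_std=float(bp.means.std()),
        peak_deviation=peak,
        peak_deviation_percent=100.0 * peak / abs(baseline),
        pre_temperature_mean=float(tp.means.mean()),
        pre_temperature_block_std=float(tp.means.std()),
        peak_temperature_deviation=float(np.max(np.abs(ta.means - tp.means.mean()))),
        initiation_time=res.initiation_time,
        result=res,
    )


@dataclass
class MorphOutcomeReport:
    post_mean_sc_distance: float  # Å, time-averaged over the post-phase
    product_sc_equilibrium: float  # Å, the product topology's bond r0
    leaving_initial_distance: float  # Å, C-L at the end of the morph
    leaving_final_distance: float  # Å, C-L at the end of the post-phase
    leaving_bonded_in_product: bool
    max_net_charge_drift: float  # over a lambda grid, |Q(lambda) - Q(0)|
    result: ProtocolResult


def run_morph_outcome_benchmark(
    seed: int = 1,
    *,
    solvent_count: int = 150,
    box_edge: float = 18.0,
    t_rxn: float = 20.0,
    update_interval: float = 1.0,
    post_phase: float = 20.0,
) -> MorphOutcomeReport:
    """Run the reaction end-to-end and measure the product geometry: the
    new S-C bond settles at its equilibrium length and the leaving ion,
    bonded to nothing, diffuses away from the carbon."""
    rng = np.random.default_rng(seed)
    fix = build_sn2_fixture(
        FixtureSpec(
            solvent_count=solvent_count, box_edge=box_edge, tether=True,
            seed=int(rng.integers(2**31)),
        )
    )
    cfg = EngineConfig(
        timestep=0.002, cutoff=8.0, constraints=True, seed=int(rng.integers(2**31))
    )
    st = equilibrate(fix, cfg, duration=6.0, rng=rng)
    sched = SwitchSchedule(t_rxn=t_rxn, update_interval=update_interval, shape="sigmoidal")
    rcfg = ReactionConfig(
        reactive_pair=fix.reactive_pair,
        pre_phase=2.0,
        segment_length=2.0,
        checkpoint_interval=0.1,
        max_watch_time=60.0,
        post_phase=post_phase,
        seed=int(rng.integers(2**31)),
    )
    res = run_protocol(
        fix.topo_reactant, fix.topo_product, fix.morph, sched, rcfg, cfg, st, rng=rng
    )
    if not res.initiated:
        raise RuntimeError("morph outcome benchmark: reaction did not initiate")
    idx = fix.indices
    post = res.trajectories["post"]
    box = res.final_state.box
    d_sc = pair_distance_series(post.frames, (idx["SG"], idx["CT"]), box)
    d_cl = pair_distance_series(post.frames, (idx["CT"], idx["L"]), box)
    sc_bond = next(
        b for b in fix.topo_product.bonds if b.key == tuple(sorted((idx["SG"], idx["CT"])))
    )
    leaving_bonded = any(idx["L"] in (b.i, b.j) for b in fix.topo_product.bonds)
    drift = 0.0
    q0 = fix.topo_reactant.net_charge()
    for lam in np.linspace(0.0, 1.0, 11):
        drift = max(drift, abs(effective_parameters(fix.morph, float(lam)).net_charge() - q0))
    return MorphOutcomeReport(
        post_mean_sc_distance=float(np.mean(d_sc)),
        product_sc_equilibrium=sc_bond.equilibrium,
        leaving_initial_distance=float(d_cl[0]),
        leaving_final_distance=float(d_cl[-1]),
        leaving_bonded_in_product=leaving_bonded,
        max_net_charge_drift=drift,
        result=res,
    )
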