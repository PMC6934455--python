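"""The master reaction protocol: watch, trigger, morph, continue.

The simulation of a covalent conjugation event proceeds in four phases:

1. **pre-phase** — conventional dynamics of the noncovalent (reactant)
   system;
2. **watch loop** — the trajectory is recorded in fixed-length segments
   with full restart checkpoints (coordinates + velocities + RNG state) at
   a regular interval; after each segment the nucleophile–electrophile
   distance series is scanned in order, and every frame below the capture
   radius r_c draws an independent Bernoulli(p0) — the first success
   initiates the reaction ("rejection sampling", which makes the modelled
   reaction slow relative to conformational dynamics);
3. **morph** — the checkpoint of the accepted frame is reloaded and the
   adiabatic reactant → product interpolation is run over T_rxn;
4. **post-phase** — conventional dynamics of the product system.

Identical configuration and seed give a bit-identical protocol result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EngineConfig, Integrator, MDResult, run_md
from .morph import MorphMap, MorphResult, SwitchSchedule, run_morph
from .system import SystemState
from .topology import Topology

__all__ = [
    "ReactionConfig",
    "Checkpoint",
    "ProtocolResult",
    "pair_distance_series",
    "find_initiation",
    "run_protocol",
]


@dataclass
class ReactionConfig:
    """Reactive pair, trigger parameters and phase durations (ps).

    Defaults mirror the published protocol scale: capture radius 3.3 Å,
    acceptance probability 0.1, 1-ns watch segments checkpointed every
    1 ps.  Desk-scale runs pass much shorter phases explicitly.
    """

    reactive_pair: tuple[int, int] = (0, 1)
    capture_radius: float = 3.3
    acceptance_probability: float = 0.1
    pre_phase: float = 0.0
    segment_length: float = 1000.0
    checkpoint_interval: float = 1.0
    max_watch_time: float = 10000.0
    post_phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.acceptance_probability <= 1.0):
            raise ValueError("acceptance probability must lie in [0, 1]")
        if self.capture_radius <= 0:
            raise ValueError("capture radius must be positive")
        ratio = self.segment_length / self.checkpoint_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("checkpoint_interval must divide segment_length")


@dataclass
class Checkpoint:
    """Restart record: everything needed to continue bit-exactly."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray | None
    rng_state: dict

    def to_state(self) -> SystemState:
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            None if self.box is None else self.box.copy(),
            self.time,
        )


@dataclass
class ProtocolResult:
    """Bookkeeping of one protocol run."""

    initiated: bool
    initiation_time: float | None
    initiation_index: int | None
    phase_boundaries: dict[str, tuple[float, float]]
    distance_times: np.ndarray
    distances: np.ndarray
    logs: dict[str, pd.DataFrame]
    trajectories: dict[str, MDResult | MorphResult] = field(default_factory=dict)
    final_state: SystemState | None = None

    def summary(self) -> dict:
        out = {
            "initiated": bool(self.initiated),
            "initiation_time_ps": self.initiation_time,
            "initiation_frame": self.initiation_index,
            "phase_boundaries_ps": {k: list(v) for k, v in self.phase_boundaries.items()},
            "n_distance_frames": int(self.distances.size),
        }
        if self.distances.size:
            out["min_distance_A"] = float(np.min(self.distances))
        return out


def pair_distance_series(
    frames, pair: tuple[int, int], box: np.ndarray | None = None
) -> np.ndarray:
    """Minimum-image distance between two atoms, one value per frame."""
    i, j = pair
    out = np.empty(len(frames))
    for f, pos in enumerate(frames):
        pos = np.asarray(pos)
        if not (0 <= i < pos.shape[0] and 0 <= j < pos.shape[0]):
            raise IndexError(f"reactive pair {pair} out of range for frame of {pos.shape[0]} atoms")
        d = pos[i] - pos[j]
        if box is not None:
            b = np.asarray(box, dtype=float)
            d = d - b * np.rint(d / b)
        out[f] = math.sqrt(float(d @ d))
    return out


def find_initiation(
    distances: np.ndarray,
    r_c: float,
    p0: float,
    rng: np.random.Generator,
) -> int | None:
    """Scan frames in order; each frame with d < r_c draws an independent
    Bernoulli(p0).  Returns the index of the first success, else None.

    A frame at exactly d == r_c does not qualify (the trigger requires the
    distance to *fall below* the capture radius).
    """
    for n, d in enumerate(np.asarray(distances, dtype=float)):
        if not math.isfinite(d):
            raise ValueError(f"non-finite distance at frame {n}")
        if d < r_c and rng.random() < p0:
            return n
    return None


def run_protocol(
    topo_reactant: Topology,
    topo_product: Topology,
    morph: MorphMap,
    schedule: SwitchSchedule,
    reaction_config: ReactionConfig,
    engine_config: EngineConfig,
    initial_state: SystemState,
    *,
    rng: np.random.Generator | None = None,
) -> ProtocolResult:
    """Execute the full pre/watch/morph/post protocol.

    The watch loop records segments of ``segment_length`` ps, saving a full
    checkpoint every ``checkpoint_interval`` ps and scanning each segment's
    distance series; when the stochastic trigger fires on checkpoint ``n``,
    the stored state of that checkpoint becomes the initial state of the
    reaction.  Exceeding ``max_watch_time`` yields a graceful "no reaction"
    result.
    """
    rcfg = reaction_config
    if rng is None:
        rng = np.random.default_rng(rcfg.seed)
    trigger_rng = np.random.default_rng(rng.integers(2**31))

    logs: dict[str, pd.DataFrame] = {}
    trajectories: dict[str, MDResult | MorphResult] = {}
    boundaries: dict[str, tuple[float, float]] = {}
    state = initial_state.copy()

    if rcfg.pre_phase > 0:
        pre = run_md(
            topo_reactant, state, engine_config, rcfg.pre_phase,
            rng=rng, save_interval=rcfg.checkpoint_interval,
        )
        boundaries["pre"] = (state.time, pre.final_state.time)
        logs["pre"] = pre.log
        trajectories["pre"] = pre
        state = pre.final_state
    else:
        boundaries["pre"] = (state.time, state.time)

    # ---- watch loop -----------------------------------------------------
    watch_start = state.time
    dist_times: list[float] = []
    distances: list[float] = []
    watch_logs: list[pd.DataFrame] = []
    initiation_ckpt: Checkpoint | None = None
    initiation_index: int | None = None
    scanned = 0

    integrator = Integrator(topo_reactant, engine_config, rng)
    while state.time - watch_start < rcfg.max_watch_time - 1e-9 and initiation_ckpt is None:
        seg_checkpoints: list[Checkpoint] = []
        n_ck = int(round(rcfg.segment_length / rcfg.checkpoint_interval))
        for _ in range(n_ck):
            seg = run_md(
                topo_reactant, state, engine_config, rcfg.checkpoint_interval,
                rng=rng, save_interval=rcfg.checkpoint_interval, integrator=integrator,
            )
            state = seg.final_state
            watch_logs.append(seg.log)
            seg_checkpoints.append(
                Checkpoint(
                    state.time,
                    state.positions.copy(),
                    state.velocities.copy(),
                    None if state.box is None else state.box.copy(),
                    rng.bit_generator.state,
                )
            )
            if state.time - watch_start >= rcfg.max_watch_time - 1e-9:
                break
        seg_dist = pair_distance_series(
            [c.positions for c in seg_checkpoints], rcfg.reactive_pair, state.box
        )
        dist_times.extend(c.time for c in seg_checkpoints)
        distances.extend(seg_dist)
        hit = find_initiation(
            seg_dist, rcfg.capture_radius, rcfg.acceptance_probability, trigger_rng
        )
        if hit is not None:
            initiation_index = scanned + hit
            initiation_ckpt = seg_checkpoints[hit]
        scanned += len(seg_checkpoints)

    boundaries["watch"] = (watch_start, state.time)
    if watch_logs:
        logs["watch"] = pd.concat(watch_logs, ignore_index=True)

    dist_times_arr = np.asarray(dist_times)
    distances_arr = np.asarray(distances)

    if initiation_ckpt is None:
        return ProtocolResult(
            initiated=False,
            initiation_time=None,
            initiation_index=None,
            phase_boundaries=boundaries,
            distance_times=dist_times_arr,
            distances=distances_arr,
            logs=logs,
            trajectories=trajectories,
            final_state=state,
        )

    # ---- reaction: reload the accepted checkpoint and morph -------------
    state = initiation_ckpt.to_state()
    rng.bit_generator.state = initiation_ckpt.rng_state
    morph_result = run_morph(
        engine_config, morph, schedule, state, rng=rng,
        save_interval=rcfg.checkpoint_interval,
    )
    state = morph_result.final_state
    boundaries["morph"] = (initiation_ckpt.time, state.time)
    logs["morph"] = morph_result.log
    trajectories["morph"] = morph_result

    if rcfg.post_phase > 0:
        post = run_md(
            topo_product, state, engine_config, rcfg.post_phase,
            rng=rng, save_interval=rcfg.checkpoint_interval,
        )
        boundaries["post"] = (state.time, post.final_state.time)
        logs["post"] = post.log
        trajectories["post"] = post
        state = post.final_state

    return ProtocolResult(
        initiated=True,
        initiation_time=initiation_ckpt.time,
        initiation_index=initiation_index,
        phase_boundaries=boundaries,
        distance_times=dist_times_arr,
        distances=distances_arr,
        logs=logs,
        trajectories=trajectories,
        final_state=state,
    )
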