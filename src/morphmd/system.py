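"""Simulation state container shared by the engine and the I/O layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SystemState:
    """Positions/velocities/box/time of one frame.

    ``box`` is either ``None`` (non-periodic) or the three edge lengths of an
    orthorhombic periodic cell in Å.  Velocities are Å/ps, time is ps.
    """

    positions: np.ndarray
    velocities: np.ndarray = None  # type: ignore[assignment]
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float | None:
        return None if self.box is None else float(np.prod(self.box))

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            None if self.box is None else self.box.copy(),
            self.time,
        )
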