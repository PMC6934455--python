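"""File I/O: the structured-text topology dialect and coordinate files.

Topology dialect
----------------
YAML document with blocks ``atoms``, ``bonds``, ``angles``, ``dihedrals``,
``restraints``, ``scaling`` and optional ``overrides``.  Angles and phases
are written in degrees (stored internally in radians); all other values are
in the package's internal units (Å, amu, elementary charges, kcal/mol).
Row layouts:

.. code-block:: yaml

    morphmd_topology: 1
    title: reactant
    scaling: {elec14: 0.8333333333333334, vdw14: 0.5}
    atoms:      # [index, name, resid, resname, mass, charge, eps, rmin_half]
      - [0, SG, 0, NUC, 32.06, -0.89, 0.25, 2.0]
    bonds:      # [i, j, k_kcal_mol_A2, r0_A, constrained]
      - [0, 1, 227.0, 1.81, false]
    angles:     # [i, j, k, k_kcal_mol_rad2, theta0_deg]
    dihedrals:  # [i, j, k, l, half_barrier, periodicity, phase_deg]
    restraints: # [i, j, k, target_A, weight, flat_bottom]
    overrides:  # [i, j, elec_scale, vdw_scale]

Coordinates
-----------
PDB (via biotite; ATOM records with 1-based serials, CRYST1 for the box) and
multi-frame XYZ (Å, free format; the comment line carries ``time=`` and
``box=`` fields when available).
"""

from __future__ import annotations

import math
import os
from typing import Sequence

import numpy as np
import yaml

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
    "read_topology",
    "write_topology",
    "read_coordinates",
    "write_coordinates",
    "read_xyz",
    "write_xyz",
    "write_morph_block",
    "read_morph_block",
    "TopologyParseError",
]

_DEG = math.pi / 180.0


class TopologyParseError(ValueError):
    pass


def write_topology(topology: Topology, path: str | os.PathLike) -> None:
    """Serialize a topology in the dialect described in the module docstring."""
    doc: dict = {"morphmd_topology": 1}
    if topology.title:
        doc["title"] = topology.title
    doc["scaling"] = {
        "elec14": float(topology.scale14_elec),
        "vdw14": float(topology.scale14_vdw),
    }
    doc["atoms"] = [
        [
            a.index,
            str(a.name),
            a.residue_index,
            str(a.residue_name),
            float(a.mass),
            float(a.charge),
            float(a.lj_epsilon),
            float(a.lj_rmin_half),
        ]
        for a in topology.atoms
    ]
    doc["bonds"] = [
        [b.i, b.j, float(b.force_constant), float(b.equilibrium), bool(b.constrained)]
        for b in topology.bonds
    ]
    doc["angles"] = [
        [a.i, a.j, a.k, float(a.force_constant), float(a.equilibrium / _DEG)]
        for a in topology.angles
    ]
    doc["dihedrals"] = [
        [d.i, d.j, d.k, d.l, float(d.barrier_half), int(d.periodicity), float(d.phase / _DEG)]
        for d in topology.dihedrals
    ]
    doc["restraints"] = [
        [r.i, r.j, float(r.force_constant), float(r.target), float(r.weight), bool(r.flat_bottom)]
        for r in topology.restraints
    ]
    if topology.nonbonded_overrides:
        doc["overrides"] = [
            [i, j, float(se), float(sv)]
            for (i, j), (se, sv) in sorted(topology.nonbonded_overrides.items())
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=True, width=10**6)


def _rows(doc: dict, block: str, width: int, path: str, required: bool = False) -> list:
    if block not in doc:
        if required:
            raise TopologyParseError(f"{path}: missing required block '{block}'")
        return []
    rows = doc[block] or []
    if not isinstance(rows, list):
        raise TopologyParseError(f"{path}: block '{block}' must be a sequence of rows")
    for k, row in enumerate(rows):
        if not isinstance(row, (list, tuple)) or len(row) != width:
            raise TopologyParseError(
                f"{path}: block '{block}' row {k}: expected {width} fields, got {row!r}"
            )
    return rows


def read_topology(path: str | os.PathLike) -> Topology:
    """Parse a topology file; malformed input raises :class:`TopologyParseError`
    naming the offending line or block."""
    path = os.fspath(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.MarkedYAMLError as exc:  # pragma: no cover - message detail
            mark = exc.problem_mark
            line = mark.line + 1 if mark is not None else "?"
            raise TopologyParseError(f"{path}: line {line}: {exc.problem}") from exc
    if not isinstance(doc, dict) or "morphmd_topology" not in doc:
        raise TopologyParseError(f"{path}: not a morphmd topology file")
    topo = Topology(title=str(doc.get("title", "")))
    scaling = doc.get("scaling", {})
    topo.scale14_elec = float(scaling.get("elec14", 1.0 / 1.2))
    topo.scale14_vdw = float(scaling.get("vdw14", 0.5))
    for row in _rows(doc, "atoms", 8, path, required=True):
        topo.atoms.append(
            AtomRecord(
                int(row[0]), str(row[1]), int(row[2]), str(row[3]),
                float(row[4]), float(row[5]), float(row[6]), float(row[7]),
            )
        )
    for row in _rows(doc, "bonds", 5, path):
        topo.bonds.append(
            BondTerm(int(row[0]), int(row[1]), float(row[2]), float(row[3]), bool(row[4]))
        )
    for row in _rows(doc, "angles", 5, path):
        topo.angles.append(
            AngleTerm(int(row[0]), int(row[1]), int(row[2]), float(row[3]), float(row[4]) * _DEG)
        )
    for row in _rows(doc, "dihedrals", 7, path):
        topo.dihedrals.append(
            DihedralTerm(
                int(row[0]), int(row[1]), int(row[2]), int(row[3]),
                float(row[4]), int(row[5]), float(row[6]) * _DEG,
            )
        )
    for row in _rows(doc, "restraints", 6, path):
        topo.restraints.append(
            DistanceRestraint(
                int(row[0]), int(row[1]), float(row[2]), float(row[3]),
                float(row[4]), bool(row[5]),
            )
        )
    for row in _rows(doc, "overrides", 4, path):
        i, j = int(row[0]), int(row[1])
        if i > j:
            i, j = j, i
        topo.nonbonded_overrides[(i, j)] = (float(row[2]), float(row[3]))
    return topo


def write_morph_block(morph, path: str | os.PathLike) -> None:
    """Serialize a morph map as a ``morph`` block in the dialect: vanish /
    appear term lists, per-pair crossfade scale factors and the two
    endpoint charge vectors."""
    doc = {
        "morphmd_morph": 1,
        "vanish": {
            "bonds": [[b.i, b.j, float(b.force_constant), float(b.equilibrium)]
                      for b in morph.vanish_bonds],
            "angles": [[a.i, a.j, a.k, float(a.force_constant), float(a.equilibrium / _DEG)]
                       for a in morph.vanish_angles],
            "dihedrals": [[d.i, d.j, d.k, d.l, float(d.barrier_half), int(d.periodicity),
                           float(d.phase / _DEG)] for d in morph.vanish_dihedrals],
        },
        "appear": {
            "bonds": [[b.i, b.j, float(b.force_constant), float(b.equilibrium)]
                      for b in morph.appear_bonds],
            "angles": [[a.i, a.j, a.k, float(a.force_constant), float(a.equilibrium / _DEG)]
                       for a in morph.appear_angles],
            "dihedrals": [[d.i, d.j, d.k, d.l, float(d.barrier_half), int(d.periodicity),
                           float(d.phase / _DEG)] for d in morph.appear_dihedrals],
        },
        "crossfade": [
            [i, j, list(cf.scale_reactant), list(cf.scale_product), cf.direction]
            for (i, j), cf in sorted(morph.pair_crossfade.items())
        ],
        "charges": {
            "reactant": [float(q) for q in morph.q_reactant],
            "product": [float(q) for q in morph.q_product],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=True, width=10**6)


def read_morph_block(path: str | os.PathLike) -> dict:
    """Read a serialized morph block back into plain dictionaries (term
    rows in the same layouts as :func:`write_morph_block`)."""
    path = os.fspath(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "morphmd_morph" not in doc:
        raise TopologyParseError(f"{path}: not a morphmd morph block")
    return doc


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


def write_xyz(
    frames: Sequence[np.ndarray],
    names: Sequence[str],
    path: str | os.PathLike,
    *,
    times: Sequence[float] | None = None,
    box: np.ndarray | None = None,
    append: bool = False,
) -> None:
    """Write one or more frames as concatenated XYZ blocks (Å, %.6f)."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for f, pos in enumerate(frames):
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (len(names), 3):
                raise ValueError("frame atom count does not match name list")
            comment = f"frame={f}"
            if times is not None:
                comment += f" time={times[f]:.6f}"
            if box is not None:
                comment += " box=" + " ".join(f"{b:.6f}" for b in np.asarray(box).ravel())
            fh.write(f"{len(names)}\n{comment}\n")
            for name, (x, y, z) in zip(names, pos):
                fh.write(f"{name:<4s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path: str | os.PathLike) -> tuple[list[np.ndarray], list[str], np.ndarray | None]:
    """Read a (multi-frame) XYZ file -> (frames, atom names, box or None)."""
    frames: list[np.ndarray] = []
    names: list[str] = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].split()[0])
        except ValueError as exc:
            raise TopologyParseError(f"{path}: line {k + 1}: expected atom count") from exc
        comment = lines[k + 1]
        if "box=" in comment:
            vals = comment.split("box=")[1].split()[:3]
            box = np.array([float(v) for v in vals])
        block = lines[k + 2 : k + 2 + n]
        if len(block) < n:
            raise TopologyParseError(f"{path}: line {k + 1}: truncated frame")
        pos = np.empty((n, 3))
        fnames = []
        for a, line in enumerate(block):
            parts = line.split()
            fnames.append(parts[0])
            pos[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not names:
            names = fnames
        frames.append(pos)
        k += 2 + n
    return frames, names, box


def write_coordinates(
    state: SystemState,
    topology: Topology,
    path: str | os.PathLike,
    fmt: str | None = None,
) -> None:
    """Write a single frame as PDB or XYZ (format inferred from suffix)."""
    fmt = _infer_format(path, fmt)
    if state.n_atoms != topology.n_atoms:
        raise ValueError(
            f"state has {state.n_atoms} atoms but topology has {topology.n_atoms}"
        )
    names = [a.name for a in topology.atoms]
    if fmt == "xyz":
        write_xyz([state.positions], names, path, times=[state.time], box=state.box)
        return
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = np.asarray(state.positions, dtype=np.float32)
    arr.atom_name = np.array(names)
    arr.res_id = np.array([a.residue_index + 1 for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.chain_id = np.array(["A"] * topology.n_atoms)
    arr.element = np.array([_guess_element(n) for n in names])
    arr.hetero = np.array([True] * topology.n_atoms)
    if state.box is not None:
        arr.box = np.diag(state.box).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(os.fspath(path))


def read_coordinates(
    path: str | os.PathLike, fmt: str | None = None
) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Read PDB or XYZ coordinates -> (list of (N,3) frames in Å, box or None)."""
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        frames, _, box = read_xyz(path)
        return frames, box
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(os.fspath(path))
    stack = pdb.get_structure()
    box = None
    if stack.box is not None:
        b = np.asarray(stack.box)
        b = b[0] if b.ndim == 3 else b
        box = np.array([b[0, 0], b[1, 1], b[2, 2]], dtype=float)
    return [np.asarray(c, dtype=float) for c in stack.coord], box


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(os.fspath(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unsupported coordinate format {fmt!r} (use pdb or xyz)")
    return fmt


def _guess_element(name: str) -> str:
    head = "".join(c for c in name if c.isalpha())[:2].upper()
    for two in ("CL", "NA", "BR", "MG", "ZN"):
        if head.startswith(two):
            return two[0] + two[1].lower()
    return head[:1] if head else "X"
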