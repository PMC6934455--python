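"""Trajectory diagnostics and NMR-oriented validation math.

Block-averaged observable traces, Kabsch superposition, per-atom RMSF,
mean-structure displacement, hydrogen-bond occupancy, combined chemical
shift perturbations (CSP), secondary-shift comparison statistics, and
pseudo-first-order kinetics fitting.

Shift tables are plain :class:`pandas.DataFrame` objects with columns
``resid``, ``resname``, ``atom``, ``nucleus``, ``shift_ppm`` and optionally
``rc_ppm`` (random-coil reference); ``sec_ppm`` (= shift − rc) is derived.
Nucleus classes follow protein-NMR convention: ``13C'`` (carbonyl),
``13Ca``, ``13Cb``, ``15N``, ``1HN``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

__all__ = [
    "TraceReport",
    "AnalysisConfig",
    "KineticsFit",
    "block_trace",
    "combined_csp",
    "read_shift_table",
    "read_predictor_table",
    "secondary_shifts",
    "ensemble_average_shifts",
    "compare_shifts",
    "superpose",
    "apply_transform",
    "superpose_trajectory",
    "rmsf",
    "mean_structure_displacement",
    "hbond_occupancy",
    "fit_first_order",
]

CARBON_CLASSES = ("13C'", "13Ca", "13Cb")

_ATOM_TO_NUCLEUS = {"C": "13C'", "CA": "13Ca", "CB": "13Cb", "N": "15N", "H": "1HN", "HN": "1HN"}


@dataclass
class AnalysisConfig:
    """Weights of the combined CSP and hydrogen-bond geometry criteria."""

    w_hn: float = 0.5
    w_n: float = 0.07
    hbond_distance_cutoff: float = 3.5  # donor-acceptor, Å
    hbond_angle_cutoff: float = 120.0  # donor-H-acceptor, degrees

    def __post_init__(self) -> None:
        if self.w_hn <= 0 or self.w_n <= 0:
            raise ValueError("CSP weights must be positive")


# ---------------------------------------------------------------------------
# block traces
# ---------------------------------------------------------------------------


@dataclass
class TraceReport:
    """Per-block mean and standard deviation of a uniformly sampled series."""

    block_length: float
    block_times: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.means.size


def block_trace(series, times, block_length: float) -> TraceReport:
    """Block statistics of a uniformly sampled series.

    Blocks are contiguous windows of ``block_length`` in the time unit of
    ``times``; a partial trailing block is dropped.  ``block_times`` are
    the window midpoints.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size != times.size:
        raise ValueError("series and times must have equal length")
    if series.size < 2:
        raise ValueError("series too short for block statistics")
    dt = float(np.median(np.diff(times)))
    per_block = int(round(block_length / dt))
    if per_block < 1 or per_block > series.size:
        raise ValueError(
            f"block length {block_length} spans {per_block} samples but the "
            f"series has {series.size}"
        )
    n_blocks = series.size // per_block
    trimmed = series[: n_blocks * per_block].reshape(n_blocks, per_block)
    ttrim = times[: n_blocks * per_block].reshape(n_blocks, per_block)
    return TraceReport(
        block_length=block_length,
        block_times=ttrim.mean(axis=1),
        means=trimmed.mean(axis=1),
        stds=trimmed.std(axis=1),
    )


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------


def combined_csp(dhn_a, dn_a, dhn_b, dn_b, w_hn: float = 0.5, w_n: float = 0.07):
    """Weighted 1HN/15N chemical-shift perturbation between two states.

    Δ = sqrt(w_HN (δHN_a − δHN_b)² + w_N (δN_a − δN_b)²), in ppm.  The
    default weights (0.5, 0.07) are the standard amide mapping weights.
    Accepts scalars or aligned arrays.
    """
    dhn = np.asarray(dhn_a, dtype=float) - np.asarray(dhn_b, dtype=float)
    dn = np.asarray(dn_a, dtype=float) - np.asarray(dn_b, dtype=float)
    out = np.sqrt(w_hn * dhn**2 + w_n * dn**2)
    return float(out) if out.ndim == 0 else out


def read_shift_table(path) -> pd.DataFrame:
    """Read a TSV shift table (columns resid, resname, atom, shift_ppm
    [, rc_ppm]); the ``nucleus`` class is derived from the atom name."""
    df = pd.read_csv(path, sep="\t")
    required = {"resid", "resname", "atom", "shift_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table {path} missing columns {sorted(missing)}")
    df["nucleus"] = df["atom"].str.upper().map(_ATOM_TO_NUCLEUS)
    if "rc_ppm" in df.columns:
        df["sec_ppm"] = df["shift_ppm"] - df["rc_ppm"]
    return df


def read_predictor_table(path) -> pd.DataFrame:
    """Adapter for the whitespace-separated per-residue tables emitted by
    common structure-based shift predictors (columns like RESID, RESNAME,
    ATOMNAME, SHIFT and optionally RC_SHIFT), normalized into the package
    schema (resid, resname, atom, nucleus, shift_ppm[, rc_ppm, sec_ppm])."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    upper = {c.upper(): c for c in df.columns}
    colmap = {}
    for ours, theirs in (
        ("resid", ("RESID", "RES_ID", "RESNUM", "NUM")),
        ("resname", ("RESNAME", "RES_NAME", "RES")),
        ("atom", ("ATOMNAME", "ATOM_NAME", "ATOM")),
        ("shift_ppm", ("SHIFT", "SHIFT_PPM", "CS")),
        ("rc_ppm", ("RC_SHIFT", "RC_PPM", "RANDOM_COIL")),
    ):
        for cand in theirs:
            if cand in upper:
                colmap[upper[cand]] = ours
                break
    df = df.rename(columns=colmap)
    missing = {"resid", "resname", "atom", "shift_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"predictor table {path}: could not map columns {sorted(missing)}")
    df["nucleus"] = df["atom"].str.upper().map(_ATOM_TO_NUCLEUS)
    if "rc_ppm" in df.columns:
        df["sec_ppm"] = df["shift_ppm"] - df["rc_ppm"]
    keep = [c for c in ("resid", "resname", "atom", "nucleus", "shift_ppm", "rc_ppm", "sec_ppm")
            if c in df.columns]
    return df[keep]


def secondary_shifts(table: pd.DataFrame, rc_catalogue: pd.DataFrame) -> pd.DataFrame:
    """Subtract random-coil reference shifts (matched on resname + atom)."""
    rc = rc_catalogue[["resname", "atom", "rc_ppm"]]
    out = table.drop(columns=[c for c in ("rc_ppm", "sec_ppm") if c in table.columns])
    out = out.merge(rc, on=["resname", "atom"], how="left")
    out["sec_ppm"] = out["shift_ppm"] - out["rc_ppm"]
    return out


def ensemble_average_shifts(
    per_frame_tables: list[pd.DataFrame],
) -> tuple[pd.DataFrame, list[tuple]]:
    """Arithmetic mean of per-frame predicted shifts.

    Tables are matched on (resid, atom); keys missing from any frame are
    dropped from the average and returned in the report list.
    """
    if not per_frame_tables:
        raise ValueError("no shift tables to average")
    n = len(per_frame_tables)
    combined = pd.concat(per_frame_tables, ignore_index=True)
    counts = combined.groupby(["resid", "atom"])["shift_ppm"].count()
    complete = counts[counts == n].index
    dropped = [tuple(k) for k in counts[counts != n].index]
    meta_cols = [c for c in ("resname", "nucleus") if c in combined.columns]
    grouped = combined.groupby(["resid", "atom"], as_index=False).agg(
        {**{c: "first" for c in meta_cols}, "shift_ppm": "mean"}
    )
    key = list(zip(grouped["resid"], grouped["atom"]))
    mask = [k in set(complete) for k in key]
    return grouped[mask].reset_index(drop=True), dropped


@dataclass
class ShiftComparison:
    per_class: pd.DataFrame  # columns: nucleus, r, rmsd, n
    skipped: list[str] = field(default_factory=list)

    def row(self, nucleus: str) -> pd.Series | None:
        m = self.per_class[self.per_class["nucleus"] == nucleus]
        return None if m.empty else m.iloc[0]


def compare_shifts(
    predicted: pd.DataFrame,
    experimental: pd.DataFrame,
    nucleus_classes=("13C'", "13Ca", "13Cb", "15N", "1HN"),
    use_secondary: bool = True,
) -> ShiftComparison:
    """Per-nucleus-class agreement between predicted and experimental
    shifts matched on (resid, atom): Pearson r, rmsd and pair count, plus a
    pooled row over the three carbon classes (nucleus ``13C``).

    With ``use_secondary`` both sides must carry ``sec_ppm`` (i.e. the same
    random-coil catalogue applied to both); classes with fewer than 3
    matched pairs are skipped with a warning.
    """
    col = "sec_ppm" if use_secondary else "shift_ppm"
    for name, df in (("predicted", predicted), ("experimental", experimental)):
        if col not in df.columns:
            raise ValueError(f"{name} table lacks column {col!r}")
    merged = predicted.merge(
        experimental, on=["resid", "atom"], suffixes=("_pred", "_exp")
    )
    nuc_col = "nucleus_pred" if "nucleus_pred" in merged.columns else "nucleus"
    rows = []
    skipped = []

    def _stats(sub):
        x = sub[f"{col}_pred"].to_numpy(dtype=float)
        y = sub[f"{col}_exp"].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 3:
            return None
        r = float(stats.pearsonr(x, y).statistic)
        rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
        return r, rmsd, x.size

    for nucleus in nucleus_classes:
        sub = merged[merged[nuc_col] == nucleus]
        res = _stats(sub)
        if res is None:
            skipped.append(nucleus)
            warnings.warn(f"nucleus class {nucleus}: fewer than 3 matched pairs, skipped")
            continue
        rows.append({"nucleus": nucleus, "r": res[0], "rmsd": res[1], "n": res[2]})
    pooled = merged[merged[nuc_col].isin(CARBON_CLASSES)]
    res = _stats(pooled)
    if res is not None:
        rows.append({"nucleus": "13C", "r": res[0], "rmsd": res[1], "n": res[2]})
    return ShiftComparison(pd.DataFrame(rows), skipped)


# ---------------------------------------------------------------------------
# structure: superposition, RMSF, displacement, hydrogen bonds
# ---------------------------------------------------------------------------


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    selected atoms; the rotation is proper (det = +1).  Raises on
    degenerate (collinear or < 3 atom) selections.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    msel = mobile[sel]
    rsel = reference[sel]
    mc = msel.mean(axis=0)
    rc = rsel.mean(axis=0)
    a = msel - mc
    # collinearity check: second singular value of the centered cloud
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) atom selection")
    rot, _ = Rotation.align_vectors(rsel - rc, a)
    rmat = rot.as_matrix()
    trans = rc - mc @ rmat.T
    fitted = msel @ rmat.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - rsel) ** 2, axis=1))))
    return rmat, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray):
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def superpose_trajectory(
    frames, reference: np.ndarray, selection=None
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using ``selection``."""
    out = np.empty((len(frames), *np.asarray(reference).shape))
    for f, frame in enumerate(frames):
        r, t, _ = superpose(frame, reference, selection)
        out[f] = apply_transform(frame, r, t)
    return out


def rmsf(
    frames,
    selection=None,
    superposition_selection=None,
    *,
    presuperposed: bool = False,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    Frames are first superposed onto the first frame over
    ``superposition_selection`` (unless ``presuperposed``); the RMSF is
    then sqrt(mean_f |r_f - <r>|^2) for each selected atom, in Å.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 1:
        warnings.warn("single frame: RMSF is identically zero")
        n = frames[0].shape[0] if selection is None else len(selection)
        return np.zeros(n)
    if presuperposed:
        stack = np.stack(frames)
    else:
        stack = superpose_trajectory(frames, frames[0], superposition_selection)
    if selection is not None:
        stack = stack[:, np.asarray(selection)]
    mean = stack.mean(axis=0)
    dev2 = np.sum((stack - mean) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def mean_structure_displacement(
    frames_a,
    frames_b,
    selection=None,
    superposition_selection=None,
) -> np.ndarray:
    """Per-atom distance between the time-averaged structures of two
    trajectories, both superposed to a common reference (first frame of
    ``frames_a``)."""
    frames_a = [np.asarray(f, dtype=float) for f in frames_a]
    frames_b = [np.asarray(f, dtype=float) for f in frames_b]
    if frames_a[0].shape != frames_b[0].shape:
        raise ValueError("trajectories have mismatched atom sets")
    ref = frames_a[0]
    mean_a = superpose_trajectory(frames_a, ref, superposition_selection).mean(axis=0)
    mean_b = superpose_trajectory(frames_b, ref, superposition_selection).mean(axis=0)
    diff = mean_a - mean_b
    if selection is not None:
        diff = diff[np.asarray(selection)]
    return np.sqrt(np.sum(diff**2, axis=1))


def hbond_occupancy(
    frames,
    donor: int,
    hydrogen: int,
    acceptor: int,
    config: AnalysisConfig | None = None,
    box: np.ndarray | None = None,
) -> float:
    """Fraction of frames with a donor/hydrogen/acceptor geometry meeting
    both the distance and the angle criterion."""
    cfg = config or AnalysisConfig()
    hits = 0
    total = 0
    for frame in frames:
        pos = np.asarray(frame, dtype=float)

        def mic(d):
            if box is not None:
                b = np.asarray(box, dtype=float)
                d = d - b * np.rint(d / b)
            return d

        da = mic(pos[acceptor] - pos[donor])
        if np.linalg.norm(da) > cfg.hbond_distance_cutoff:
            total += 1
            continue
        hd = mic(pos[donor] - pos[hydrogen])
        ha = mic(pos[acceptor] - pos[hydrogen])
        cosang = float(hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if angle >= cfg.hbond_angle_cutoff:
            hits += 1
        total += 1
    return hits / total if total else 0.0


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticsFit:
    amplitude: float
    plateau: float
    half_life: float  # same time unit as the input
    residual: float  # rms of fit residuals
    identifiable: bool = True


class KineticsFitError(RuntimeError):
    pass


def fit_first_order(times, intensities, direction: str = "decay") -> KineticsFit:
    """Least-squares pseudo-first-order (exponential) kinetics fit.

    decay:   I(t) = A exp(−t ln2 / τ½) + c
    buildup: I(t) = A (1 − exp(−t ln2 / τ½)) + c

    Returns the fitted half-life τ½ in the unit of ``times``.  A fit whose
    amplitude is negligible against the data scale is flagged
    ``identifiable=False`` (τ½ meaningless for a constant series).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points for a kinetics fit")
    if direction not in ("decay", "buildup"):
        raise ValueError("direction must be 'decay' or 'buildup'")
    span = float(y.max() - y.min())
    scale = max(span, abs(float(y.mean())), 1e-12)
    if span < 1e-12 * scale:
        return KineticsFit(0.0, float(y.mean()), math.inf, 0.0, identifiable=False)

    def model(t, a, tau, c):
        e = np.exp(-t * math.log(2.0) / tau)
        return a * e + c if direction == "decay" else a * (1.0 - e) + c

    tau0 = max((t.max() - t.min()) / 2.0, 1e-6)
    a0 = span if direction == "buildup" else (y[0] - y[-1])
    c0 = y[-1] if direction == "decay" else y[0]
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(a0, tau0, c0),
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise KineticsFitError(f"kinetics fit did not converge: {exc}") from exc
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    a, tau, c = (float(v) for v in popt)
    identifiable = abs(a) > 1e-6 * scale and math.isfinite(tau)
    return KineticsFit(a, c, tau, resid, identifiable)
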