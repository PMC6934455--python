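"""Numba-compiled inner loops for the MD engine.

All kernels accumulate forces in-place into a preallocated (N, 3) array and
return scalar energies plus the pairwise virial sum ``W = sum r_ij . f_ij``
(kcal/mol), which the engine converts into a pressure.  Periodicity is the
orthorhombic minimum-image convention; ``box`` entries <= 0 mean
non-periodic along every axis (the engine passes a sentinel).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Coulomb prefactor, kcal·Å/(mol·e²) — duplicated from topology.py because
#: numba kernels cannot read module-level Python constants cheaply at call time.
_COULOMB = 332.0637


@njit(cache=True, fastmath=True, inline="always")
def _min_image(dx, dy, dz, bx, by, bz):
    if bx > 0.0:
        dx -= bx * np.rint(dx / bx)
        dy -= by * np.rint(dy / by)
        dz -= bz * np.rint(dz / bz)
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def bond_kernel(pos, box, idx, kcon, r0, forces):
    """Harmonic bonds E = k (r - r0)^2. Returns (energy, virial)."""
    e = 0.0
    w = 0.0
    bx, by, bz = box[0], box[1], box[2]
    for t in range(idx.shape[0]):
        i = idx[t, 0]
        j = idx[t, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[t]
        e += kcon[t] * dr * dr
        # force on i along +d: f = -dE/dr = -2 k dr
        f_over_r = -2.0 * kcon[t] * dr / r
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        w += fx * dx + fy * dy + fz * dz
    return e, w


@njit(cache=True, fastmath=True)
def restraint_kernel(pos, box, idx, kcon, target, weight, flat, forces):
    """Weight-scaled distance restraints, optionally flat-bottomed."""
    e = 0.0
    w = 0.0
    bx, by, bz = box[0], box[1], box[2]
    for t in range(idx.shape[0]):
        keff = weight[t] * kcon[t]
        if keff == 0.0:
            continue
        i = idx[t, 0]
        j = idx[t, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - target[t]
        if flat[t] and dr <= 0.0:
            continue
        e += keff * dr * dr
        f_over_r = -2.0 * keff * dr / r
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        w += fx * dx + fy * dy + fz * dz
    return e, w


@njit(cache=True, fastmath=True)
def angle_kernel(pos, box, idx, kcon, theta0, forces):
    """Harmonic angles E = k (theta - theta0)^2."""
    e = 0.0
    w = 0.0
    bx, by, bz = box[0], box[1], box[2]
    for t in range(idx.shape[0]):
        i = idx[t, 0]
        j = idx[t, 1]
        k = idx[t, 2]
        # arms relative to the central atom j (minimum image)
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        cx = pos[k, 0] - pos[j, 0]
        cy = pos[k, 1] - pos[j, 1]
        cz = pos[k, 2] - pos[j, 2]
        ax, ay, az = _min_image(ax, ay, az, bx, by, bz)
        cx, cy, cz = _min_image(cx, cy, cz, bx, by, bz)
        ra2 = ax * ax + ay * ay + az * az
        rc2 = cx * cx + cy * cy + cz * cz
        ra = np.sqrt(ra2)
        rc = np.sqrt(rc2)
        cosq = (ax * cx + ay * cy + az * cz) / (ra * rc)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = np.arccos(cosq)
        dt = theta - theta0[t]
        e += kcon[t] * dt * dt
        # dE/dtheta
        dedt = 2.0 * kcon[t] * dt
        sinq = np.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            sinq = 1e-8
        coef = dedt / sinq
        # d(cos theta)/d r_i etc.
        fix = coef * (cx / (ra * rc) - cosq * ax / ra2)
        fiy = coef * (cy / (ra * rc) - cosq * ay / ra2)
        fiz = coef * (cz / (ra * rc) - cosq * az / ra2)
        fkx = coef * (ax / (ra * rc) - cosq * cx / rc2)
        fky = coef * (ay / (ra * rc) - cosq * cy / rc2)
        fkz = coef * (az / (ra * rc) - cosq * cz / rc2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        w += fix * ax + fiy * ay + fiz * az + fkx * cx + fky * cy + fkz * cz
    return e, w


@njit(cache=True, fastmath=True)
def dihedral_kernel(pos, box, idx, vhalf, period, phase, forces):
    """Cosine dihedrals E = (V_n/2)(1 + cos(n phi - gamma))."""
    e = 0.0
    w = 0.0
    bx, by, bz = box[0], box[1], box[2]
    for t in range(idx.shape[0]):
        i = idx[t, 0]
        j = idx[t, 1]
        k = idx[t, 2]
        l = idx[t, 3]
        # bond vectors, minimum image
        b1x, b1y, b1z = _min_image(
            pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1], pos[j, 2] - pos[i, 2], bx, by, bz
        )
        b2x, b2y, b2z = _min_image(
            pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1], pos[k, 2] - pos[j, 2], bx, by, bz
        )
        b3x, b3y, b3z = _min_image(
            pos[l, 0] - pos[k, 0], pos[l, 1] - pos[k, 1], pos[l, 2] - pos[k, 2], bx, by, bz
        )
        # normals
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue  # collinear: torsion undefined, zero contribution
        # signed dihedral angle
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        xcomp = n1x * n2x + n1y * n2y + n1z * n2z
        ycomp = (mx * n2x + my * n2y + mz * n2z) / b2n
        phi = np.arctan2(ycomp, xcomp)
        n = period[t]
        e += vhalf[t] * (1.0 + np.cos(n * phi - phase[t]))
        dedphi = -vhalf[t] * n * np.sin(n * phi - phase[t])
        # analytic derivatives (standard force decomposition)
        fi = dedphi * b2n / n1sq
        fl = -dedphi * b2n / n2sq
        fix = -fi * n1x
        fiy = -fi * n1y
        fiz = -fi * n1z
        flx = -fl * n2x
        fly = -fl * n2y
        flz = -fl * n2z
        b12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        b32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        sx = b12 * fix - b32 * flx
        sy = b12 * fiy - b32 * fly
        sz = b12 * fiz - b32 * flz
        fjx = -fix - sx
        fjy = -fiy - sy
        fjz = -fiz - sz
        fkx = -flx + sx
        fky = -fly + sy
        fkz = -flz + sz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
        # virial from local (unwrapped) coordinates relative to atom i
        px_j, py_j, pz_j = b1x, b1y, b1z
        px_k, py_k, pz_k = b1x + b2x, b1y + b2y, b1z + b2z
        px_l, py_l, pz_l = px_k + b3x, py_k + b3y, pz_k + b3z
        w += (
            fjx * px_j + fjy * py_j + fjz * pz_j
            + fkx * px_k + fky * py_k + fkz * pz_k
            + flx * px_l + fly * py_l + flz * pz_l
        )
    return e, w


@njit(cache=True, fastmath=True)
def nonbonded_kernel(pos, box, pairs, qq, epsij, rmij, cutoff, shifted, forces):
    """LJ + Coulomb over an explicit pair list with precombined parameters.

    ``qq`` already carries the Coulomb prefactor, both charges and any
    per-pair scale factor; ``epsij``/``rmij`` are the combined (and scaled)
    LJ well depth and minimum position.  Coulomb is force-shifted at the
    cutoff when ``shifted`` is true (energy and force both continuous at
    r_c); LJ is plainly truncated.  A non-finite ``cutoff`` disables
    truncation (gas-phase mode).  Returns (evdw, ecoul, virial, min_r2):
    ``min_r2`` lets the caller detect singular overlaps without branching
    in the hot loop.
    """
    evdw = 0.0
    ecoul = 0.0
    w = 0.0
    bx, by, bz = box[0], box[1], box[2]
    use_cut = np.isfinite(cutoff)
    rc = cutoff if use_cut else 1.0
    rc2 = rc * rc
    inv_rc = 1.0 / rc
    inv_rc2 = inv_rc * inv_rc
    min_r2 = 1e30
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
        r2 = dx * dx + dy * dy + dz * dz
        if use_cut and r2 >= rc2:
            continue
        if r2 < min_r2:
            min_r2 = r2
        if r2 < 1e-10:
            continue  # singular; the caller raises via min_r2
        inv_r2 = 1.0 / r2
        inv_r = np.sqrt(inv_r2)
        r = r2 * inv_r
        if use_cut and shifted:
            ec = qq[p] * (inv_r + r * inv_rc2 - 2.0 * inv_rc)
            fc = qq[p] * (inv_r2 - inv_rc2)  # -dE/dr
        else:
            ec = qq[p] * inv_r
            fc = qq[p] * inv_r2
        rm = rmij[p]
        sr2 = rm * rm * inv_r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        ev = epsij[p] * (sr12 - 2.0 * sr6)
        if use_cut:
            # energy-shift the LJ to zero at the cutoff (forces unchanged):
            # keeps the total energy continuous as pairs cross r_c
            src2 = rm * rm / rc2
            src6 = src2 * src2 * src2
            ev -= epsij[p] * (src6 * src6 - 2.0 * src6)
        fv = 12.0 * epsij[p] * (sr12 - sr6) * inv_r  # -dE/dr
        ecoul += ec
        evdw += ev
        f_over_r = (fc + fv) * inv_r
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        w += fx * dx + fy * dy + fz * dz
    return evdw, ecoul, w, min_r2


@njit(cache=True, fastmath=True)
def build_pairs(
    pos, box, rlist2, excl_start, excl_j, q, seps, rminh,
    pairs, qq, epsij, rmij,
):
    """One-pass O(N^2) Verlet-list build with per-pair parameter assembly.

    ``excl_start``/``excl_j`` form a CSR map atom i -> sorted excluded or
    special partners j > i (walked incrementally, so the exclusion test is
    O(1) amortized).  ``seps`` is sqrt(lj_epsilon) per atom.  Returns the
    number of pairs written, or -1 if the preallocated arrays are too
    small (caller grows them and retries).
    """
    bx, by, bz = box[0], box[1], box[2]
    n = pos.shape[0]
    cap = pairs.shape[0]
    m = 0
    for i in range(n):
        p = excl_start[i]
        pend = excl_start[i + 1]
        for j in range(i + 1, n):
            while p < pend and excl_j[p] < j:
                p += 1
            if p < pend and excl_j[p] == j:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if m >= cap:
                    return -1
                pairs[m, 0] = i
                pairs[m, 1] = j
                qq[m] = _COULOMB * q[i] * q[j]
                epsij[m] = seps[i] * seps[j]
                rmij[m] = rminh[i] + rminh[j]
                m += 1
    return m


@njit(cache=True, fastmath=True)
def max_displacement2(pos, ref):
    """Largest squared displacement of any atom since the list build."""
    worst = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > worst:
            worst = d2
    return worst


@njit(cache=True, fastmath=True)
def shake_positions(pos, ref, box, idx, r0, invmass, tol, max_iter):
    """Iterative bond-length constraint (SHAKE). Returns iterations used,
    or -1 on non-convergence.  ``tol`` is relative: |r - r0| / r0.

    Corrections are applied along the *reference* bond directions (the
    geometry at the start of the step), the classic choice that keeps the
    integrator time-reversible and non-dissipative.
    """
    bx, by, bz = box[0], box[1], box[2]
    n = idx.shape[0]
    for it in range(max_iter):
        worst = 0.0
        for t in range(n):
            i = idx[t, 0]
            j = idx[t, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            err = abs(r - r0[t]) / r0[t]
            if err > worst:
                worst = err
            if err <= tol:
                continue
            rx = ref[i, 0] - ref[j, 0]
            ry = ref[i, 1] - ref[j, 1]
            rz = ref[i, 2] - ref[j, 2]
            rx, ry, rz = _min_image(rx, ry, rz, bx, by, bz)
            dot = dx * rx + dy * ry + dz * rz
            if abs(dot) < 1e-12:
                dot = 1e-12  # pathological geometry: fall back gracefully
            g = (r2 - r0[t] * r0[t]) / (2.0 * (invmass[i] + invmass[j]) * dot)
            pos[i, 0] -= g * invmass[i] * rx
            pos[i, 1] -= g * invmass[i] * ry
            pos[i, 2] -= g * invmass[i] * rz
            pos[j, 0] += g * invmass[j] * rx
            pos[j, 1] += g * invmass[j] * ry
            pos[j, 2] += g * invmass[j] * rz
        if worst <= tol:
            return it + 1
    return -1


@njit(cache=True, fastmath=True)
def rattle_velocities(pos, vel, box, idx, invmass, tol, max_iter):
    """Remove relative velocity components along each constraint (RATTLE).
    Returns iterations used, or -1 on non-convergence."""
    bx, by, bz = box[0], box[1], box[2]
    n = idx.shape[0]
    for it in range(max_iter):
        worst = 0.0
        for t in range(n):
            i = idx[t, 0]
            j = idx[t, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
            r2 = dx * dx + dy * dy + dz * dz
            vrel = (
                (vel[i, 0] - vel[j, 0]) * dx
                + (vel[i, 1] - vel[j, 1]) * dy
                + (vel[i, 2] - vel[j, 2]) * dz
            )
            err = abs(vrel) / np.sqrt(r2)
            if err > worst:
                worst = err
            if err <= tol:
                continue
            g = vrel / (r2 * (invmass[i] + invmass[j]))
            vel[i, 0] -= g * invmass[i] * dx
            vel[i, 1] -= g * invmass[i] * dy
            vel[i, 2] -= g * invmass[i] * dz
            vel[j, 0] += g * invmass[j] * dx
            vel[j, 1] += g * invmass[j] * dy
            vel[j, 2] += g * invmass[j] * dz
        if worst <= tol:
            return it + 1
    return -1
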