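"""Numba kernels: bonded forces and the BAOAB Langevin integrator.

Everything here operates on flat numpy arrays in reduced units (length nm,
energy k_B*T_ref, mass = one subunit).  The public API lives in
:mod:`actinmech.dynamics`; these kernels are implementation detail.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# integrator status codes
STATUS_OK = 0
STATUS_UNSTABLE = 1

# external-force event modes
MODE_EXPLICIT = 0
MODE_AXIAL = 1
MODE_TORQUE = 2


@njit(cache=True, fastmath=True)
def bonded_forces(pos, forces,
                  bonds, bond_l0, bond_intact, k_l,
                  angles, angle_theta0, angle_active, k_theta,
                  dihedrals, dihedral_phi0, dihedral_active, k_phi, n_mult):
    """Accumulate bonded forces into ``forces``; return per-term energies."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    v_bond = 0.0
    for b in range(bonds.shape[0]):
        if not bond_intact[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = r - bond_l0[b]
        v_bond += 0.5 * k_l * dl * dl
        f = k_l * dl / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    v_angle = 0.0
    for a in range(angles.shape[0]):
        if not angle_active[a]:
            continue
        j = angles[a, 0]
        i = angles[a, 1]
        k = angles[a, 2]
        ux = pos[j, 0] - pos[i, 0]
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = pos[k, 0] - pos[i, 0]
        vy = pos[k, 1] - pos[i, 1]
        vz = pos[k, 2] - pos[i, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_theta0[a]
        v_angle += 0.5 * k_theta * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            continue  # force direction undefined at straight angle
        coef = k_theta * dth / s
        # dtheta/dp_j and dtheta/dp_k
        gjx = (vx / nv - c * ux / nu) / nu
        gjy = (vy / nv - c * uy / nu) / nu
        gjz = (vz / nv - c * uz / nu) / nu
        gkx = (ux / nu - c * vx / nv) / nv
        gky = (uy / nu - c * vy / nv) / nv
        gkz = (uz / nu - c * vz / nv) / nv
        # F = -dV/dtheta * dtheta/dp ; dtheta/dp = -(1/s) * dcos/dp
        fjx = coef * gjx
        fjy = coef * gjy
        fjz = coef * gjz
        fkx = coef * gkx
        fky = coef * gky
        fkz = coef * gkz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[i, 0] -= fjx + fkx
        forces[i, 1] -= fjy + fky
        forces[i, 2] -= fjz + fkz

    v_dih = 0.0
    for d in range(dihedrals.shape[0]):
        if not dihedral_active[d]:
            continue
        p0 = dihedrals[d, 0]
        p1 = dihedrals[d, 1]
        p2 = dihedrals[d, 2]
        p3 = dihedrals[d, 3]
        b1x = pos[p1, 0] - pos[p0, 0]
        b1y = pos[p1, 1] - pos[p0, 1]
        b1z = pos[p1, 2] - pos[p0, 2]
        b2x = pos[p2, 0] - pos[p1, 0]
        b2y = pos[p2, 1] - pos[p1, 1]
        b2z = pos[p2, 2] - pos[p1, 2]
        b3x = pos[p3, 0] - pos[p2, 0]
        b3y = pos[p3, 1] - pos[p2, 1]
        b3z = pos[p3, 2] - pos[p2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / nb2
        phi = np.arctan2(y, x)
        dphi = n_mult * phi - dihedral_phi0[d]
        v_dih += k_phi * (1.0 - np.cos(dphi))
        dv = k_phi * n_mult * np.sin(dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # gradients of phi (atan2 convention above), verified against
        # central finite differences:
        # dphi/dp0 = +|b2|/|n1|^2 n1 ; dphi/dp3 = -|b2|/|n2|^2 n2
        # dphi/dp1 = -(1+s12) g0 + s32 g3 ; dphi/dp2 = s12 g0 - (1+s32) g3
        g0x = nb2 / n1sq * n1x
        g0y = nb2 / n1sq * n1y
        g0z = nb2 / n1sq * n1z
        g3x = -nb2 / n2sq * n2x
        g3y = -nb2 / n2sq * n2y
        g3z = -nb2 / n2sq * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g1x = -(1.0 + s12) * g0x + s32 * g3x
        g1y = -(1.0 + s12) * g0y + s32 * g3y
        g1z = -(1.0 + s12) * g0z + s32 * g3z
        g2x = s12 * g0x - (1.0 + s32) * g3x
        g2y = s12 * g0y - (1.0 + s32) * g3y
        g2z = s12 * g0z - (1.0 + s32) * g3z
        forces[p0, 0] -= dv * g0x
        forces[p0, 1] -= dv * g0y
        forces[p0, 2] -= dv * g0z
        forces[p1, 0] -= dv * g1x
        forces[p1, 1] -= dv * g1y
        forces[p1, 2] -= dv * g1z
        forces[p2, 0] -= dv * g2x
        forces[p2, 1] -= dv * g2y
        forces[p2, 2] -= dv * g2z
        forces[p3, 0] -= dv * g3x
        forces[p3, 1] -= dv * g3y
        forces[p3, 2] -= dv * g3z

    return v_bond, v_angle, v_dih


@njit(cache=True)
def _apply_external(pos, forces, step,
                    ev_sub, ev_start, ev_end, ev_mode, ev_sign, ev_mag, ev_vec,
                    axis_from, axis_to):
    """Add scheduled external forces for this step."""
    n = pos.shape[0]
    # follower axis: unit vector between the two group centroids
    axx = 0.0
    axy = 0.0
    axz = 0.0
    have_axis = axis_from.shape[0] > 0 and axis_to.shape[0] > 0
    if have_axis:
        f0x = 0.0
        f0y = 0.0
        f0z = 0.0
        for t in range(axis_from.shape[0]):
            f0x += pos[axis_from[t], 0]
            f0y += pos[axis_from[t], 1]
            f0z += pos[axis_from[t], 2]
        f0x /= axis_from.shape[0]
        f0y /= axis_from.shape[0]
        f0z /= axis_from.shape[0]
        f1x = 0.0
        f1y = 0.0
        f1z = 0.0
        for t in range(axis_to.shape[0]):
            f1x += pos[axis_to[t], 0]
            f1y += pos[axis_to[t], 1]
            f1z += pos[axis_to[t], 2]
        f1x /= axis_to.shape[0]
        f1y /= axis_to.shape[0]
        f1z /= axis_to.shape[0]
        axx = f1x - f0x
        axy = f1y - f0y
        axz = f1z - f0z
        norm = np.sqrt(axx * axx + axy * axy + axz * axz)
        if norm > 1e-12:
            axx /= norm
            axy /= norm
            axz /= norm

    for e in range(ev_sub.shape[0]):
        if step < ev_start[e] or step >= ev_end[e]:
            continue
        i = ev_sub[e]
        mode = ev_mode[e]
        if mode == MODE_EXPLICIT:
            forces[i, 0] += ev_vec[e, 0]
            forces[i, 1] += ev_vec[e, 1]
            forces[i, 2] += ev_vec[e, 2]
        elif mode == MODE_AXIAL:
            f = ev_sign[e] * ev_mag[e]
            forces[i, 0] += f * axx
            forces[i, 1] += f * axy
            forces[i, 2] += f * axz
        elif mode == MODE_TORQUE:
            # rotation axis from midpoints of the last three subunits
            m1x = 0.5 * (pos[n - 1, 0] + pos[n - 2, 0])
            m1y = 0.5 * (pos[n - 1, 1] + pos[n - 2, 1])
            m1z = 0.5 * (pos[n - 1, 2] + pos[n - 2, 2])
            m2x = 0.5 * (pos[n - 2, 0] + pos[n - 3, 0])
            m2y = 0.5 * (pos[n - 2, 1] + pos[n - 3, 1])
            m2z = 0.5 * (pos[n - 2, 2] + pos[n - 3, 2])
            ux = m1x - m2x
            uy = m1y - m2y
            uz = m1z - m2z
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            if un < 1e-12:
                continue
            ux /= un
            uy /= un
            uz /= un
            # lever: position minus its projection onto the axis line
            px = pos[i, 0] - m2x
            py = pos[i, 1] - m2y
            pz = pos[i, 2] - m2z
            proj = px * ux + py * uy + pz * uz
            lx = px - proj * ux
            ly = py - proj * uy
            lz = pz - proj * uz
            ln = np.sqrt(lx * lx + ly * ly + lz * lz)
            if ln < 1e-12:
                continue
            # force direction: cross(lever, axis), scaled by sense
            dx = ly * uz - lz * uy
            dy = lz * ux - lx * uz
            dz = lx * uy - ly * ux
            dn = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dn < 1e-12:
                continue
            f = ev_sign[e] * ev_mag[e]
            forces[i, 0] += f * dx / dn
            forces[i, 1] += f * dy / dn
            forces[i, 2] += f * dz / dn


@njit(cache=True)
def _project_constraints_vec(arr, fixed_mask, rigid):
    """Zero fixed entries, average over the rigid group."""
    n = arr.shape[0]
    for i in range(n):
        if fixed_mask[i]:
            arr[i, 0] = 0.0
            arr[i, 1] = 0.0
            arr[i, 2] = 0.0
    m = rigid.shape[0]
    if m > 0:
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for t in range(m):
            sx += arr[rigid[t], 0]
            sy += arr[rigid[t], 1]
            sz += arr[rigid[t], 2]
        sx /= m
        sy /= m
        sz /= m
        for t in range(m):
            arr[rigid[t], 0] = sx
            arr[rigid[t], 1] = sy
            arr[rigid[t], 2] = sz


@njit(cache=True)
def run_langevin(pos, vel, dt, gamma, kT, n_steps, frame_interval, seed,
                 bonds, bond_l0, bond_class, bond_intact, k_l,
                 angles, angle_theta0, angle_active, k_theta,
                 dihedrals, dihedral_phi0, dihedral_active, k_phi, n_mult,
                 angle_bonds, dihedral_bonds,
                 fixed_mask, rigid,
                 ev_sub, ev_start, ev_end, ev_mode, ev_sign, ev_mag, ev_vec,
                 axis_from, axis_to,
                 rupture_enabled, l_crit_diag, l_crit_long, dwell_steps,
                 max_disp,
                 frames, frame_intact, times,
                 rupture_steps, rupture_bonds):
    """BAOAB Langevin integration with constraints and irreversible rupture.

    Returns (status, n_frames_written, n_ruptures).  Positions/velocities are
    updated in place; snapshots land in ``frames`` every ``frame_interval``
    steps (frame 0 is the initial state).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    over_count = np.zeros(bonds.shape[0], dtype=np.int64)
    c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    n_rupture = 0

    # frame 0
    frames[0] = pos
    for b in range(bonds.shape[0]):
        frame_intact[0, b] = bond_intact[b]
    times[0] = 0.0
    fcount = 1

    bonded_forces(pos, forces, bonds, bond_l0, bond_intact, k_l,
                  angles, angle_theta0, angle_active, k_theta,
                  dihedrals, dihedral_phi0, dihedral_active, k_phi, n_mult)
    _apply_external(pos, forces, 0, ev_sub, ev_start, ev_end, ev_mode,
                    ev_sign, ev_mag, ev_vec, axis_from, axis_to)
    _project_constraints_vec(forces, fixed_mask, rigid)

    for step in range(n_steps):
        # B
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
        _project_constraints_vec(vel, fixed_mask, rigid)
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O
        if gamma > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[i, 2]
            _project_constraints_vec(vel, fixed_mask, rigid)
        # A
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # force refresh + B
        bonded_forces(pos, forces, bonds, bond_l0, bond_intact, k_l,
                      angles, angle_theta0, angle_active, k_theta,
                      dihedrals, dihedral_phi0, dihedral_active, k_phi, n_mult)
        _apply_external(pos, forces, step + 1, ev_sub, ev_start, ev_end,
                        ev_mode, ev_sign, ev_mag, ev_vec, axis_from, axis_to)
        _project_constraints_vec(forces, fixed_mask, rigid)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
        _project_constraints_vec(vel, fixed_mask, rigid)

        # stability guard: displacement per step bounded by a subunit size
        vmax = 0.0
        for i in range(n):
            v2 = (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                  + vel[i, 2] * vel[i, 2])
            if v2 > vmax:
                vmax = v2
        if np.sqrt(vmax) * dt > max_disp:
            return STATUS_UNSTABLE, fcount, n_rupture

        # irreversible rupture check: a bond severs once it stays beyond its
        # critical length for ``dwell_steps`` consecutive steps (sustained
        # mechanical overextension, as opposed to a fleeting thermal peak)
        if rupture_enabled:
            for b in range(bonds.shape[0]):
                if not bond_intact[b]:
                    continue
                i = bonds[b, 0]
                j = bonds[b, 1]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                thr = l_crit_diag if bond_class[b] == 0 else l_crit_long
                if r > thr:
                    over_count[b] += 1
                else:
                    over_count[b] = 0
                if over_count[b] >= dwell_steps:
                    bond_intact[b] = False
                    rupture_steps[n_rupture] = step + 1
                    rupture_bonds[n_rupture] = b
                    n_rupture += 1
                    for a in range(angle_bonds.shape[0]):
                        for t in range(angle_bonds.shape[1]):
                            if angle_bonds[a, t] == b:
                                angle_active[a] = False
                    for d in range(dihedral_bonds.shape[0]):
                        for t in range(dihedral_bonds.shape[1]):
                            if dihedral_bonds[d, t] == b:
                                dihedral_active[d] = False

        if (step + 1) % frame_interval == 0:
            frames[fcount] = pos
            for b in range(bonds.shape[0]):
                frame_intact[fcount, b] = bond_intact[b]
            times[fcount] = (step + 1) * dt
            fcount += 1

    return STATUS_OK, fcount, n_rupture
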