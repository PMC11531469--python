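"""Numba kernels for energies, forces and the Langevin inner loop."""

import numpy as np
from numba import njit


@njit(cache=True)
def _bonded_forces(pos, forces,
                   bond_idx, bond_r0, bond_k,
                   ang_idx, ang_t0, ang_k,
                   dih_idx, dih_p0, dih_k):
    e_bond = 0.0
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            raise ValueError("zero bond length encountered")
        dr = r - bond_r0[b]
        e_bond += bond_k[b] * dr * dr
        f = -2.0 * bond_k[b] * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    e_ang = 0.0
    for a in range(ang_idx.shape[0]):
        i, j, k = ang_idx[a, 0], ang_idx[a, 1], ang_idx[a, 2]
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        cost = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        dth = theta - ang_t0[a]
        e_ang += ang_k[a] * dth * dth
        dv = 2.0 * ang_k[a] * dth
        for d in range(3):
            dti = (cost * u[d] / nu - v[d] / nv) / (nu * sint)
            dtk = (cost * v[d] / nv - u[d] / nu) / (nv * sint)
            fi = -dv * dti
            fk = -dv * dtk
            forces[i, d] += fi
            forces[k, d] += fk
            forces[j, d] -= fi + fk

    e_dih = 0.0
    for t in range(dih_idx.shape[0]):
        i, j, k, l = dih_idx[t, 0], dih_idx[t, 1], dih_idx[t, 2], dih_idx[t, 3]
        b1 = pos[j] - pos[i]
        b2 = pos[k] - pos[j]
        b3 = pos[l] - pos[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue  # collinear — dihedral undefined, zero contribution
        m = np.cross(n1, n2)
        y = (m[0] * b2[0] + m[1] * b2[1] + m[2] * b2[2]) / nb2
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(y, x)
        dphi = phi - dih_p0[t]
        e_dih += dih_k[t] * (1.0 - np.cos(dphi))
        dv = dih_k[t] * np.sin(dphi)
        gi = -nb2 / n1sq * n1
        gl = nb2 / n2sq * n2
        s12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        s32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for d in range(3):
            gj = -(1.0 + s12) * gi[d] + s32 * gl[d]
            gk = -gi[d] - gl[d] - gj  # translation invariance
            forces[i, d] -= dv * gi[d]
            forces[j, d] -= dv * gj
            forces[k, d] -= dv * gk
            forces[l, d] -= dv * gl[d]
    return e_bond, e_ang, e_dih


@njit(cache=True)
def _go_forces(pos, forces, con_idx, con_r0, con_eps, con_set, con_sigma,
               e_go):
    for c in range(con_idx.shape[0]):
        i, j = con_idx[c, 0], con_idx[c, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            raise ValueError("overlapping contact pair (zero distance)")
        s = con_sigma[con_set[c]]
        q = con_r0[c] / r
        q10 = q ** 10
        q12 = q10 * q * q
        e_go[con_set[c]] += s * con_eps[c] * (5.0 * q12 - 6.0 * q10)
        # dV/dr = s*eps*60/r*(q10 - q12); force along r̂ is -dV/dr
        f = -s * con_eps[c] * 60.0 * (q10 - q12) / (r * r)
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz


@njit(cache=True)
def _nonbonded_forces(pos, forces, q_intra, q_cross, is_dna, radii, nb_mask,
                      kappa, ke_eff, dh_cutoff, dh_shift, eps_ev):
    n = pos.shape[0]
    e_ev = 0.0
    e_dh = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            m = nb_mask[i, j]
            if m == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < 1e-12:
                raise ValueError("zero nonbonded distance")
            # excluded volume (mask 2 = contact pair, Gō well handles it)
            if m == 0:
                d = radii[i] + radii[j]
                if r < d:
                    q = (d / r) ** 12
                    e_ev += eps_ev * (q - 1.0)
                    f = 12.0 * eps_ev * q / r2
                    forces[i, 0] += f * dx
                    forces[i, 1] += f * dy
                    forces[i, 2] += f * dz
                    forces[j, 0] -= f * dx
                    forces[j, 1] -= f * dy
                    forces[j, 2] -= f * dz
            # Debye-Hückel with context-dependent phosphate charges
            if is_dna[i] == 1 and is_dna[j] == 1:
                qq = q_intra[i] * q_intra[j]
            else:
                qq = q_cross[i] * q_cross[j]
            if qq != 0.0:
                if dh_cutoff > 0.0 and r > dh_cutoff:
                    continue
                u = ke_eff * qq * np.exp(-kappa * r) / r
                if dh_shift and dh_cutoff > 0.0:
                    u -= ke_eff * qq * np.exp(-kappa * dh_cutoff) / dh_cutoff
                e_dh += u
                fmag = ke_eff * qq * np.exp(-kappa * r) * (kappa * r + 1.0) / (r2 * r)
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
    return e_ev, e_dh


@njit(cache=True)
def _external_forces(pos, forces, conf_on, conf_center, conf_radius, conf_k,
                     restraint_idx, restraint_x0, restraint_k):
    e_conf = 0.0
    if conf_on:
        for i in range(pos.shape[0]):
            dx = pos[i, 0] - conf_center[0]
            dy = pos[i, 1] - conf_center[1]
            dz = pos[i, 2] - conf_center[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > conf_radius:
                dr = r - conf_radius
                e_conf += conf_k * dr * dr
                f = -2.0 * conf_k * dr / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
    e_res = 0.0
    for t in range(restraint_idx.shape[0]):
        i = restraint_idx[t]
        for d in range(3):
            dx = pos[i, d] - restraint_x0[t, d]
            e_res += restraint_k[t] * dx * dx
            forces[i, d] -= 2.0 * restraint_k[t] * dx
    return e_conf, e_res


@njit(cache=True)
def compute_forces(pos, forces,
                   bond_idx, bond_r0, bond_k,
                   ang_idx, ang_t0, ang_k,
                   dih_idx, dih_p0, dih_k,
                   con_idx, con_r0, con_eps, con_set, con_sigma, e_go,
                   q_intra, q_cross, is_dna, radii, nb_mask,
                   kappa, ke_eff, dh_cutoff, dh_shift, eps_ev,
                   conf_on, conf_center, conf_radius, conf_k,
                   restraint_idx, restraint_x0, restraint_k):
    """Fill ``forces`` and ``e_go`` (per contact set); return scalar terms."""
    forces[:] = 0.0
    e_go[:] = 0.0
    e_bond, e_ang, e_dih = _bonded_forces(pos, forces, bond_idx, bond_r0,
                                          bond_k, ang_idx, ang_t0, ang_k,
                                          dih_idx, dih_p0, dih_k)
    _go_forces(pos, forces, con_idx, con_r0, con_eps, con_set, con_sigma, e_go)
    e_ev, e_dh = _nonbonded_forces(pos, forces, q_intra, q_cross, is_dna,
                                   radii, nb_mask, kappa, ke_eff, dh_cutoff,
                                   dh_shift, eps_ev)
    e_conf, e_res = _external_forces(pos, forces, conf_on, conf_center,
                                     conf_radius, conf_k, restraint_idx,
                                     restraint_x0, restraint_k)
    return e_bond, e_ang, e_dih, e_ev, e_dh, e_conf, e_res


@njit(cache=True)
def baoab_chunk(pos, vel, masses, n_steps, dt, gamma, kbt, seed,
                bond_idx, bond_r0, bond_k,
                ang_idx, ang_t0, ang_k,
                dih_idx, dih_p0, dih_k,
                con_idx, con_r0, con_eps, con_set, con_sigma, e_go,
                q_intra, q_cross, is_dna, radii, nb_mask,
                kappa, ke_eff, dh_cutoff, dh_shift, eps_ev,
                conf_on, conf_center, conf_radius, conf_k,
                restraint_idx, restraint_x0, restraint_k):
    """Integrate ``n_steps`` of BAOAB Langevin dynamics in place.

    Returns the potential energy after the last step.  The friction step is
    the exact Ornstein-Uhlenbeck solve, so the velocity marginal is sampled
    exactly at every O sub-step.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    pot = 0.0
    terms = compute_forces(pos, forces,
                           bond_idx, bond_r0, bond_k, ang_idx, ang_t0, ang_k,
                           dih_idx, dih_p0, dih_k,
                           con_idx, con_r0, con_eps, con_set, con_sigma, e_go,
                           q_intra, q_cross, is_dna, radii, nb_mask,
                           kappa, ke_eff, dh_cutoff, dh_shift, eps_ev,
                           conf_on, conf_center, conf_radius, conf_k,
                           restraint_idx, restraint_x0, restraint_k)
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] / masses[i]
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        # O: exact OU
        for i in range(n):
            c2 = np.sqrt((1.0 - c1 * c1) * kbt / masses[i])
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += 0.5 * dt * vel[i, d]
        terms = compute_forces(pos, forces,
                               bond_idx, bond_r0, bond_k, ang_idx, ang_t0,
                               ang_k, dih_idx, dih_p0, dih_k,
                               con_idx, con_r0, con_eps, con_set, con_sigma,
                               e_go, q_intra, q_cross, is_dna, radii, nb_mask,
                               kappa, ke_eff, dh_cutoff, dh_shift, eps_ev,
                               conf_on, conf_center, conf_radius, conf_k,
                               restraint_idx, restraint_x0, restraint_k)
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] / masses[i]
        pot = (terms[0] + terms[1] + terms[2] + terms[3] + terms[4]
               + terms[5] + terms[6])
        for s in range(e_go.shape[0]):
            pot += e_go[s]
    return pot
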