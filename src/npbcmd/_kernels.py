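"""Numba kernels for the O(N²) charge sums and pairwise interactions.

All kernels are serial (fixed summation order) so trajectories are
bit-reproducible for a given seed.  Electrostatic prefactors (k_e) are
applied by the callers.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def potential_at_points(targets, positions, charges, rmin=0.0):
    """Σ_k q_k / |t - r_k| at each target point (no k_e)."""
    nt = targets.shape[0]
    nk = positions.shape[0]
    out = np.zeros(nt)
    for n in range(nt):
        acc = 0.0
        for k in range(nk):
            dx = targets[n, 0] - positions[k, 0]
            dy = targets[n, 1] - positions[k, 1]
            dz = targets[n, 2] - positions[k, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rmin:
                r = rmin
            acc += charges[k] / r
        out[n] = acc
    return out


@njit(cache=True, fastmath=False)
def field_at_points(targets, positions, charges, rmin=0.0):
    """Field Σ_k q_k (t - r_k)/|t - r_k|³ at each target (no k_e)."""
    nt = targets.shape[0]
    nk = positions.shape[0]
    out = np.zeros((nt, 3))
    for n in range(nt):
        ex = ey = ez = 0.0
        for k in range(nk):
            dx = targets[n, 0] - positions[k, 0]
            dy = targets[n, 1] - positions[k, 1]
            dz = targets[n, 2] - positions[k, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < rmin:
                r = rmin
                r2 = rmin * rmin
            inv3 = charges[k] / (r2 * r)
            ex += dx * inv3
            ey += dy * inv3
            ez += dz * inv3
        out[n, 0] = ex
        out[n, 1] = ey
        out[n, 2] = ez
    return out


@njit(cache=True, fastmath=False)
def pair_kernel(pos, charges, sigma, epsilon, mol, mol_com, ke, forces):
    """All-pairs LJ 12-6 + Coulomb between atoms of different molecules.

    Forces are accumulated into ``forces`` (must be zeroed by the caller).
    Returns (E_LJ, E_Coulomb, molecular virial Σ R_AB·f_ij, n_overlap).
    The virial uses molecule COM separations, the origin-independent form
    appropriate for rigid molecular pressure.
    """
    n = pos.shape[0]
    e_lj = 0.0
    e_c = 0.0
    w = 0.0
    n_overlap = 0
    for i in range(n - 1):
        mi = mol[i]
        for j in range(i + 1, n):
            if mol[j] == mi:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1.0e-12:
                n_overlap += 1
                continue
            inv_r2 = 1.0 / r2
            fscal = 0.0
            if epsilon[i] > 0.0 and epsilon[j] > 0.0:
                sij = 0.5 * (sigma[i] + sigma[j])
                eij = np.sqrt(epsilon[i] * epsilon[j])
                sr2 = sij * sij * inv_r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                e_lj += 4.0 * eij * (sr12 - sr6)
                fscal += 24.0 * eij * (2.0 * sr12 - sr6) * inv_r2
            qq = charges[i] * charges[j]
            if qq != 0.0:
                r = np.sqrt(r2)
                e_c += ke * qq / r
                fscal += ke * qq / (r2 * r)
            fx = fscal * dx
            fy = fscal * dy
            fz = fscal * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            mj = mol[j]
            w += (fx * (mol_com[mi, 0] - mol_com[mj, 0])
                  + fy * (mol_com[mi, 1] - mol_com[mj, 1])
                  + fz * (mol_com[mi, 2] - mol_com[mj, 2]))
    return e_lj, e_c, w, n_overlap


@njit(cache=True, fastmath=False)
def potential_at_points_smeared(targets, positions, charges, width):
    """Σ_k q_k erf(|t-r_k|/width) / |t-r_k| — Gaussian-smeared charges.

    Beyond 4 widths the smeared potential is Coulombic to 1.5e-8 and the
    erf is skipped.
    """
    nt = targets.shape[0]
    nk = positions.shape[0]
    out = np.zeros(nt)
    two_over_sqrt_pi = 1.1283791670955126
    r_sat = 4.0 * width
    for n in range(nt):
        acc = 0.0
        for k in range(nk):
            dx = targets[n, 0] - positions[k, 0]
            dy = targets[n, 1] - positions[k, 1]
            dz = targets[n, 2] - positions[k, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > r_sat:
                acc += charges[k] / r
            elif r < 1.0e-9:
                acc += charges[k] * two_over_sqrt_pi / width
            else:
                acc += charges[k] * math.erf(r / width) / r
        out[n] = acc
    return out


@njit(cache=True, fastmath=False)
def rf_pair_kernel(nodes, s_hat, node_q, positions, charges, width,
                   atom_field):
    """Fused node/atom pass for the reaction-field forces.

    Fills ``atom_field`` with the (smeared) field of the node charges at
    each atom and returns Σ_n Q_n s_n·E_solute(x_n), the boundary-field
    term of the volume derivative, in the same smeared interaction.
    """
    nn = nodes.shape[0]
    nk = positions.shape[0]
    two_over_sqrt_pi = 1.1283791670955126
    r_sat = 4.0 * width
    radial = 0.0
    for n in range(nn):
        qn = node_q[n]
        sx, sy, sz = s_hat[n, 0], s_hat[n, 1], s_hat[n, 2]
        for k in range(nk):
            dx = nodes[n, 0] - positions[k, 0]
            dy = nodes[n, 1] - positions[k, 1]
            dz = nodes[n, 2] - positions[k, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < 1.0e-9:
                continue
            if r > r_sat:
                scal = 1.0 / (r2 * r)
            else:
                u = r / width
                scal = (math.erf(u) / r2
                        - two_over_sqrt_pi * np.exp(-u * u) / (width * r)) / r
            atom_field[k, 0] -= qn * scal * dx
            atom_field[k, 1] -= qn * scal * dy
            atom_field[k, 2] -= qn * scal * dz
            radial += qn * charges[k] * scal * (sx * dx + sy * dy + sz * dz)
    return radial


@njit(cache=True, fastmath=False)
def field_at_points_smeared(targets, positions, charges, width):
    """Field of Gaussian-smeared charges (bounded everywhere)."""
    nt = targets.shape[0]
    nk = positions.shape[0]
    out = np.zeros((nt, 3))
    two_over_sqrt_pi = 1.1283791670955126
    for n in range(nt):
        ex = ey = ez = 0.0
        for k in range(nk):
            dx = targets[n, 0] - positions[k, 0]
            dy = targets[n, 1] - positions[k, 1]
            dz = targets[n, 2] - positions[k, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < 1.0e-9:
                continue
            u = r / width
            scal = charges[k] * (math.erf(u) / r2
                                 - two_over_sqrt_pi
                                 * np.exp(-u * u) / (width * r)) / r
            ex += dx * scal
            ey += dy * scal
            ez += dz * scal
        out[n, 0] = ex
        out[n, 1] = ey
        out[n, 2] = ez
    return out


@njit(cache=True, fastmath=False)
def rvv_rotation(q, l_half, inertia, live, dt, eps, max_iter):
    """Self-consistent quaternion midpoint update for all rigid bodies.

    Quaternions are scalar-first, A(q) maps body to space:
    q̇ = ½ q ∘ (0, ω_body) with ω_body = I⁻¹ A(q)ᵀ L.  Returns the new
    (renormalized) quaternions and the number of non-converged bodies.
    """
    nb = q.shape[0]
    out = np.empty_like(q)
    n_fail = 0
    for b in range(nb):
        if not live[b]:
            out[b] = q[b]
            continue
        w0, x0, y0, z0 = q[b, 0], q[b, 1], q[b, 2], q[b, 3]
        lx, ly, lz = l_half[b, 0], l_half[b, 1], l_half[b, 2]
        ix, iy, iz = inertia[b, 0], inertia[b, 1], inertia[b, 2]
        # initial derivative from q(t)
        qw, qx, qy, qz = w0, x0, y0, z0
        dw = dx = dy = dz = 0.0
        converged = False
        for it in range(max_iter + 1):
            # ω_body = A(q)ᵀ L / I  (Aᵀ rows are A columns)
            ox = ((1 - 2 * (qy * qy + qz * qz)) * lx
                  + 2 * (qx * qy + qw * qz) * ly
                  + 2 * (qx * qz - qw * qy) * lz) / ix
            oy = (2 * (qx * qy - qw * qz) * lx
                  + (1 - 2 * (qx * qx + qz * qz)) * ly
                  + 2 * (qy * qz + qw * qx) * lz) / iy
            oz = (2 * (qx * qz + qw * qy) * lx
                  + 2 * (qy * qz - qw * qx) * ly
                  + (1 - 2 * (qx * qx + qy * qy)) * lz) / iz
            # q̇ = ½ q ∘ (0, ω)
            ndw = 0.5 * (-qx * ox - qy * oy - qz * oz)
            ndx = 0.5 * (qw * ox + qy * oz - qz * oy)
            ndy = 0.5 * (qw * oy - qx * oz + qz * ox)
            ndz = 0.5 * (qw * oz + qx * oy - qy * ox)
            delta = max(abs(ndw - dw), abs(ndx - dx),
                        abs(ndy - dy), abs(ndz - dz))
            dw, dx, dy, dz = ndw, ndx, ndy, ndz
            if it > 0 and delta < eps:
                converged = True
                break
            # midpoint quaternion for the next sweep
            qw = w0 + 0.5 * dt * dw
            qx = x0 + 0.5 * dt * dx
            qy = y0 + 0.5 * dt * dy
            qz = z0 + 0.5 * dt * dz
            inv = 1.0 / np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw *= inv
            qx *= inv
            qy *= inv
            qz *= inv
        if not converged:
            n_fail += 1
        nw = w0 + dt * dw
        nx = x0 + dt * dx
        ny = y0 + dt * dy
        nz = z0 + dt * dz
        inv = 1.0 / np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        out[b, 0] = nw * inv
        out[b, 1] = nx * inv
        out[b, 2] = ny * inv
        out[b, 3] = nz * inv
    return out, n_fail


@njit(cache=True, fastmath=False)
def min_pair_distance(pos):
    n = pos.shape[0]
    best = 1.0e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return np.sqrt(best)


@njit(cache=True, fastmath=False)
def min_intermolecular_distance(pos, mol):
    n = pos.shape[0]
    best = 1.0e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return np.sqrt(best)
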