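"""Compiled Monte Carlo kernels (numba).

These implement the same energy model as :mod:`nucleomc.energy` in a form the
JIT compiler can specialize: flat arrays, explicit loops, no Python objects.
The test suite cross-validates the kernel total energy against the numpy
reference and the incremental deltas against recomputed totals (bookkeeping
drift), so the two routes stay independent.

Move types, driven by ``run_chunk``:
  0  single-particle translation (uniform cube, side 2·amplitude)
  1  rigid chain translation (uniform cube)
  2  slither: one end monomer of the polymer chain regrown at the opposite
     end with bond length and chain angle drawn from their Boltzmann
     densities (Jacobian-complete), so only the nonbonded + confinement
     energy enters the Metropolis exponent.

The kernel RNG is numba's internal numpy-compatible stream, seeded once per
chunk by the caller; reproducibility is per (seed, chunk) pair.
"""

import math

import numpy as np
from numba import njit

INF = math.inf

#: max ΔU (kT) for which exp(−ΔU) is evaluated; larger is rejected outright
_EXP_CAP = 500.0


@njit(cache=True, inline="always")
def _dist(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, inline="always")
def _lj(r, eps, sigma):
    x = sigma / r
    x6 = x * x * x * x * x * x
    return 4.0 * eps * (x6 * x6 - x6)


@njit(cache=True)
def _angle_deg(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Angle at (bx,by,bz) between the two bond vectors, degrees."""
    ux = ax - bx
    uy = ay - by
    uz = az - bz
    vx = cx - bx
    vy = cy - by
    vz = cz - bz
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.degrees(math.acos(c))


@njit(cache=True)
def _angle_deg_override(pos, a, b, c, i, nx, ny, nz):
    """Chain angle at b with particle i's coordinate replaced by (nx,ny,nz)."""
    ax, ay, az = pos[a, 0], pos[a, 1], pos[a, 2]
    bx, by, bz = pos[b, 0], pos[b, 1], pos[b, 2]
    cx, cy, cz = pos[c, 0], pos[c, 1], pos[c, 2]
    if a == i:
        ax, ay, az = nx, ny, nz
    if b == i:
        bx, by, bz = nx, ny, nz
    if c == i:
        cx, cy, cz = nx, ny, nz
    return _angle_deg(ax, ay, az, bx, by, bz, cx, cy, cz)


@njit(cache=True)
def total_energy_arrays(
    pos, charge, radius, chain_id, chain_start, chain_len, chain_ang,
    is_hns, r_cell, lb, eps_pp, sigma_pp, lj_intra,
    k_bond, r0, k_ang, alpha0,
):
    """Full energy decomposition (u_elec_hs, u_lj, u_bond, u_angle, u_ext)."""
    n = pos.shape[0]
    u_ext = 0.0
    rc2 = r_cell * r_cell
    for i in range(n):
        if pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2 >= rc2:
            u_ext = INF
    u_elec = 0.0
    u_lj = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            r = _dist(pos, i, j)
            if r < radius[i] + radius[j]:
                u_elec = INF
            elif charge[i] != 0.0 and charge[j] != 0.0:
                u_elec += lb * charge[i] * charge[j] / r
            if eps_pp > 0.0 and is_hns[i] and is_hns[j]:
                if lj_intra or chain_id[i] != chain_id[j]:
                    u_lj += _lj(r, eps_pp, sigma_pp)
    u_bond = 0.0
    u_angle = 0.0
    for c in range(chain_start.shape[0]):
        s = chain_start[c]
        e = s + chain_len[c] - 1
        for i in range(s, e):
            dr = _dist(pos, i, i + 1) - r0
            u_bond += 0.5 * k_bond * dr * dr
        if chain_ang[c]:
            for m in range(s + 1, e):
                a = _angle_deg(
                    pos[m - 1, 0], pos[m - 1, 1], pos[m - 1, 2],
                    pos[m, 0], pos[m, 1], pos[m, 2],
                    pos[m + 1, 0], pos[m + 1, 1], pos[m + 1, 2],
                )
                da = a - alpha0
                u_angle += 0.5 * k_ang * da * da
    return u_elec, u_lj, u_bond, u_angle, u_ext


@njit(cache=True)
def _delta_nonbonded(
    pos, charge, radius, chain_id, is_hns, r_cell, lb, eps_pp, sigma_pp,
    lj_intra, i, nx, ny, nz,
):
    """Nonbonded + confinement ΔU of moving particle i to (nx,ny,nz)."""
    if nx * nx + ny * ny + nz * nz >= r_cell * r_cell:
        return INF
    n = pos.shape[0]
    qi = charge[i]
    ri = radius[i]
    hi = is_hns[i]
    ci = chain_id[i]
    du = 0.0
    for j in range(n):
        if j == i:
            continue
        dxn = nx - pos[j, 0]
        dyn = ny - pos[j, 1]
        dzn = nz - pos[j, 2]
        rn2 = dxn * dxn + dyn * dyn + dzn * dzn
        contact = ri + radius[j]
        if rn2 < contact * contact:
            return INF
        rn = math.sqrt(rn2)
        ro = _dist(pos, i, j)
        qj = charge[j]
        if qi != 0.0 and qj != 0.0:
            du += lb * qi * qj * (1.0 / rn - 1.0 / ro)
        if eps_pp > 0.0 and hi and is_hns[j]:
            if lj_intra or chain_id[j] != ci:
                du += _lj(rn, eps_pp, sigma_pp) - _lj(ro, eps_pp, sigma_pp)
    return du


@njit(cache=True)
def _delta_single(
    pos, charge, radius, chain_id, chain_start, chain_len, chain_ang,
    is_hns, r_cell, lb, eps_pp, sigma_pp, lj_intra,
    k_bond, r0, k_ang, alpha0, i, nx, ny, nz,
):
    """Total ΔU (bonded + nonbonded + confinement) of a single-particle move."""
    du = _delta_nonbonded(
        pos, charge, radius, chain_id, is_hns, r_cell, lb, eps_pp, sigma_pp,
        lj_intra, i, nx, ny, nz,
    )
    if du == INF:
        return INF
    ci = chain_id[i]
    if ci >= 0:
        s = chain_start[ci]
        e = s + chain_len[ci] - 1  # last member
        for nb in (i - 1, i + 1):
            if s <= nb <= e:
                dxn = nx - pos[nb, 0]
                dyn = ny - pos[nb, 1]
                dzn = nz - pos[nb, 2]
                rn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
                ro = _dist(pos, i, nb)
                du += 0.5 * k_bond * ((rn - r0) ** 2 - (ro - r0) ** 2)
        if chain_ang[ci]:
            for m in (i - 1, i, i + 1):
                if s + 1 <= m <= e - 1:
                    an = _angle_deg_override(pos, m - 1, m, m + 1, i, nx, ny, nz)
                    ao = _angle_deg(
                        pos[m - 1, 0], pos[m - 1, 1], pos[m - 1, 2],
                        pos[m, 0], pos[m, 1], pos[m, 2],
                        pos[m + 1, 0], pos[m + 1, 1], pos[m + 1, 2],
                    )
                    du += 0.5 * k_ang * ((an - alpha0) ** 2 - (ao - alpha0) ** 2)
    return du


@njit(cache=True)
def _delta_chain_translate(
    pos, charge, radius, chain_id, chain_start, chain_len, is_hns,
    r_cell, lb, eps_pp, sigma_pp, c, dx, dy, dz,
):
    """ΔU of a rigid chain translation: intra-chain terms are invariant, so
    only chain-vs-rest nonbonded terms and confinement are evaluated."""
    n = pos.shape[0]
    s = chain_start[c]
    e = s + chain_len[c]
    rc2 = r_cell * r_cell
    for m in range(s, e):
        nx = pos[m, 0] + dx
        ny = pos[m, 1] + dy
        nz = pos[m, 2] + dz
        if nx * nx + ny * ny + nz * nz >= rc2:
            return INF
    du = 0.0
    for m in range(s, e):
        nx = pos[m, 0] + dx
        ny = pos[m, 1] + dy
        nz = pos[m, 2] + dz
        qm = charge[m]
        rm = radius[m]
        hm = is_hns[m]
        for j in range(n):
            if chain_id[j] == c:
                continue
            dxn = nx - pos[j, 0]
            dyn = ny - pos[j, 1]
            dzn = nz - pos[j, 2]
            rn2 = dxn * dxn + dyn * dyn + dzn * dzn
            contact = rm + radius[j]
            if rn2 < contact * contact:
                return INF
            rn = math.sqrt(rn2)
            ro = _dist(pos, m, j)
            qj = charge[j]
            if qm != 0.0 and qj != 0.0:
                du += lb * qm * qj * (1.0 / rn - 1.0 / ro)
            if eps_pp > 0.0 and hm and is_hns[j]:
                du += _lj(rn, eps_pp, sigma_pp) - _lj(ro, eps_pp, sigma_pp)
    return du


@njit(cache=True)
def _draw_bond_length(k_bond, r0):
    """Sample r from p(r) ∝ r² exp(−k_bond(r−r0)²/2) by rejection against the
    bare Gaussian (weight (r/r_cap)², r_cap = r0 + 5σ)."""
    sigma = 1.0 / math.sqrt(k_bond)
    cap = r0 + 5.0 * sigma
    for _ in range(10000):
        r = r0 + np.random.normal() * sigma
        if r <= 0.0:
            continue
        w = 1.0 if r >= cap else (r / cap) * (r / cap)
        if np.random.random() < w:
            return r
    return r0


@njit(cache=True)
def _draw_chain_angle(k_ang, alpha0):
    """Sample α (deg) from p(α) ∝ sinα exp(−k_ang(α−α0)²/2) on [0, 180]."""
    if k_ang * 8100.0 < 1e-12:  # angular term effectively absent
        return math.degrees(math.acos(2.0 * np.random.random() - 1.0))
    sigma = 1.0 / math.sqrt(k_ang)
    for _ in range(10000):
        a = alpha0 - abs(np.random.normal() * sigma)
        if a < 0.0 or a > 180.0:
            continue
        if np.random.random() < math.sin(math.radians(a)):
            return a
    return alpha0 - sigma


@njit(cache=True)
def _metropolis(du):
    if du == INF:
        return False
    if du <= 0.0:
        return True
    if du > _EXP_CAP:
        return False
    return np.random.random() < math.exp(-du)


@njit(cache=True)
def run_chunk(
    pos, charge, radius, chain_id, chain_start, chain_len, chain_ang,
    is_hns, r_cell, lb, eps_pp, sigma_pp, lj_intra,
    k_bond, r0, k_ang, alpha0,
    n_attempts, amp_monomer, amp_free, amp_chain,
    p_single, p_chain, slither_chain,
    seed, counters, u_acc,
):
    """Run ``n_attempts`` Metropolis trial moves in place.

    counters: int64 (4, 2) array, [move class, attempted/accepted]; classes
    are 0 = single-particle on a chain monomer, 1 = single-particle on a
    free particle, 2 = chain translation, 3 = slither.  Chain monomers and
    free particles carry separate amplitudes: bond constraints cap useful
    monomer steps near the bond length while free ions tolerate much larger
    ones, so one shared amplitude would starve whichever class is rarer.
    u_acc: float64 (1,) running total energy, updated by accepted deltas.
    p_single / p_chain: selection probabilities (slither takes the rest);
    the caller zeroes probabilities of inapplicable move types.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_chains = chain_start.shape[0]
    thr1 = p_single
    thr2 = p_single + p_chain
    for _ in range(n_attempts):
        u = np.random.random()
        if u < thr1:
            # --- single-particle translation
            i = np.random.randint(0, n)
            cls = 0 if chain_id[i] >= 0 else 1
            amp = amp_monomer if cls == 0 else amp_free
            nx = pos[i, 0] + (2.0 * np.random.random() - 1.0) * amp
            ny = pos[i, 1] + (2.0 * np.random.random() - 1.0) * amp
            nz = pos[i, 2] + (2.0 * np.random.random() - 1.0) * amp
            counters[cls, 0] += 1
            du = _delta_single(
                pos, charge, radius, chain_id, chain_start, chain_len,
                chain_ang, is_hns, r_cell, lb, eps_pp, sigma_pp, lj_intra,
                k_bond, r0, k_ang, alpha0, i, nx, ny, nz,
            )
            if _metropolis(du):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                u_acc[0] += du
                counters[cls, 1] += 1
        elif u < thr2:
            # --- rigid chain translation
            c = np.random.randint(0, n_chains)
            dx = (2.0 * np.random.random() - 1.0) * amp_chain
            dy = (2.0 * np.random.random() - 1.0) * amp_chain
            dz = (2.0 * np.random.random() - 1.0) * amp_chain
            counters[2, 0] += 1
            du = _delta_chain_translate(
                pos, charge, radius, chain_id, chain_start, chain_len,
                is_hns, r_cell, lb, eps_pp, sigma_pp, c, dx, dy, dz,
            )
            if _metropolis(du):
                s = chain_start[c]
                for m in range(s, s + chain_len[c]):
                    pos[m, 0] += dx
                    pos[m, 1] += dy
                    pos[m, 2] += dz
                u_acc[0] += du
                counters[2, 1] += 1
        else:
            # --- slither (reptation) on the polymer chain
            c = slither_chain
            s = chain_start[c]
            length = chain_len[c]
            counters[3, 0] += 1
            from_head = np.random.randint(0, 2) == 0
            if from_head:
                i_rm = s
                anchor = s + length - 1
                anchor2 = s + length - 2
                old_nb = s + 1          # bond partner of the removed end
                old_ang_m = s + 1       # angle triple removed at this center
            else:
                i_rm = s + length - 1
                anchor = s
                anchor2 = s + 1
                old_nb = s + length - 2
                old_ang_m = s + length - 2
            ux = pos[anchor, 0] - pos[anchor2, 0]
            uy = pos[anchor, 1] - pos[anchor2, 1]
            uz = pos[anchor, 2] - pos[anchor2, 2]
            un = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= un
            uy /= un
            uz /= un
            rr = _draw_bond_length(k_bond, r0)
            has_ang = chain_ang[c] and length >= 3
            if has_ang:
                alpha = _draw_chain_angle(k_ang, alpha0)
            else:
                alpha = math.degrees(math.acos(2.0 * np.random.random() - 1.0))
            theta = math.radians(180.0 - alpha)
            phi = 2.0 * math.pi * np.random.random()
            # orthonormal frame around u
            if abs(ux) < 0.9:
                ax, ay, az = 1.0, 0.0, 0.0
            else:
                ax, ay, az = 0.0, 1.0, 0.0
            e1x = uy * az - uz * ay
            e1y = uz * ax - ux * az
            e1z = ux * ay - uy * ax
            e1n = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= e1n
            e1y /= e1n
            e1z /= e1n
            e2x = uy * e1z - uz * e1y
            e2y = uz * e1x - ux * e1z
            e2z = ux * e1y - uy * e1x
            st = math.sin(theta)
            ct = math.cos(theta)
            dxu = ct * ux + st * (math.cos(phi) * e1x + math.sin(phi) * e2x)
            dyu = ct * uy + st * (math.cos(phi) * e1y + math.sin(phi) * e2y)
            dzu = ct * uz + st * (math.cos(phi) * e1z + math.sin(phi) * e2z)
            nx = pos[anchor, 0] + rr * dxu
            ny = pos[anchor, 1] + rr * dyu
            nz = pos[anchor, 2] + rr * dzu
            du_nb = _delta_nonbonded(
                pos, charge, radius, chain_id, is_hns, r_cell, lb,
                eps_pp, sigma_pp, lj_intra, i_rm, nx, ny, nz,
            )
            if _metropolis(du_nb):
                # full ΔU for the energy books: generation bias cancelled the
                # bond+angle factors in the acceptance, not in the energy
                r_old = _dist(pos, i_rm, old_nb)
                du = du_nb + 0.5 * k_bond * ((rr - r0) ** 2 - (r_old - r0) ** 2)
                if has_ang:
                    a_old = _angle_deg(
                        pos[old_ang_m - 1, 0], pos[old_ang_m - 1, 1],
                        pos[old_ang_m - 1, 2],
                        pos[old_ang_m, 0], pos[old_ang_m, 1], pos[old_ang_m, 2],
                        pos[old_ang_m + 1, 0], pos[old_ang_m + 1, 1],
                        pos[old_ang_m + 1, 2],
                    )
                    du += 0.5 * k_ang * (
                        (alpha - alpha0) ** 2 - (a_old - alpha0) ** 2
                    )
                if from_head:
                    for m in range(s, s + length - 1):
                        pos[m, 0] = pos[m + 1, 0]
                        pos[m, 1] = pos[m + 1, 1]
                        pos[m, 2] = pos[m + 1, 2]
                    pos[s + length - 1, 0] = nx
                    pos[s + length - 1, 1] = ny
                    pos[s + length - 1, 2] = nz
                else:
                    for m in range(s + length - 1, s, -1):
                        pos[m, 0] = pos[m - 1, 0]
                        pos[m, 1] = pos[m - 1, 1]
                        pos[m, 2] = pos[m - 1, 2]
                    pos[s, 0] = nx
                    pos[s, 1] = ny
                    pos[s, 2] = nz
                u_acc[0] += du
                counters[3, 1] += 1
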