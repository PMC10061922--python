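"""Numba kernels for the bead-spring engine.

Everything here works on plain arrays in reduced units.  Pair interactions are
12-6 LJ with per-species-pair strength, cutoff and energy shift supplied as
5x5 tables (the WCA mode is just a shorter cutoff with a +epsilon shift).
Bonds are FENE springs combined with a unit-epsilon WCA core; bonded pairs are
excluded from the nonbonded sum.

Error codes returned by the integrator:
0 ok, 1 bond overstretched, 2 non-finite coordinates, 3 pair singularity.
"""

import numpy as np
from numba import njit

FENE_K = 30.0
FENE_R0 = 1.5
_WCA_RC2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2
_R2_MIN = 1e-12


@njit(cache=True, fastmath=True)
def build_neighbor_list(pos, box, rlist, max_neigh):
    """Half (i<j) Verlet list as CSR arrays; cell-binned when the box allows.

    Returns (neighbors, start, ok); ok=False means max_neigh was too small.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    counts = np.zeros(n, dtype=np.int64)
    neigh = np.empty(n * max_neigh, dtype=np.int32)

    ncx = int(box[0] // rlist)
    ncy = int(box[1] // rlist)
    ncz = int(box[2] // rlist)
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3

    if not use_cells:
        # z-sorted sweep: slab boxes prune most pairs by the z gate
        order = np.argsort(pos[:, 2]).astype(np.int32)
        zs = np.empty(n)
        for a in range(n):
            zs[a] = pos[order[a], 2]
        for a in range(n):
            i = order[a]
            ci = counts[i]
            base = i * max_neigh
            xi_ = pos[i, 0]
            yi_ = pos[i, 1]
            zi_ = zs[a]
            b = a + 1
            while b < n:
                dz = zs[b] - zi_
                if dz >= rlist:
                    break
                j = order[b]
                dx = xi_ - pos[j, 0]
                if dx > hx:
                    dx -= box[0]
                elif dx < -hx:
                    dx += box[0]
                dy = yi_ - pos[j, 1]
                if dy > hy:
                    dy -= box[1]
                elif dy < -hy:
                    dy += box[1]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rl2:
                    if ci >= max_neigh:
                        return neigh, counts, False
                    neigh[base + ci] = j
                    ci += 1
                b += 1
            counts[i] = ci
        # periodic wrap across the z boundary: top band vs bottom band
        a = n - 1
        while a >= 0 and zs[a] > box[2] - rlist:
            i = order[a]
            ci = counts[i]
            base = i * max_neigh
            xi_ = pos[i, 0]
            yi_ = pos[i, 1]
            zi_ = zs[a]
            b = 0
            while b < n and zs[b] + box[2] - zi_ < rlist:
                j = order[b]
                if j != i:
                    dz = zs[b] + box[2] - zi_
                    dx = xi_ - pos[j, 0]
                    if dx > hx:
                        dx -= box[0]
                    elif dx < -hx:
                        dx += box[0]
                    dy = yi_ - pos[j, 1]
                    if dy > hy:
                        dy -= box[1]
                    elif dy < -hy:
                        dy += box[1]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rl2:
                        if ci >= max_neigh:
                            return neigh, counts, False
                        neigh[base + ci] = j
                        ci += 1
                b += 1
            counts[i] = ci
            a -= 1
    else:
        ncell = ncx * ncy * ncz
        lx = box[0] / ncx
        ly = box[1] / ncy
        lz = box[2] / ncz
        head = -np.ones(ncell, dtype=np.int64)
        nxt = -np.ones(n, dtype=np.int64)
        cell_of = np.empty(n, dtype=np.int64)
        for i in range(n):
            cx = int(pos[i, 0] / lx) % ncx
            cy = int(pos[i, 1] / ly) % ncy
            cz = int(pos[i, 2] / lz) % ncz
            c = (cz * ncy + cy) * ncx + cx
            cell_of[i] = c
            nxt[i] = head[c]
            head[c] = i
        for i in range(n):
            ci = 0
            base = i * max_neigh
            c = cell_of[i]
            cx = c % ncx
            cy = (c // ncx) % ncy
            cz = c // (ncx * ncy)
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    for oz in range(-1, 2):
                        nc = (((cz + oz) % ncz) * ncy + (cy + oy) % ncy) * ncx \
                            + (cx + ox) % ncx
                        j = head[nc]
                        while j >= 0:
                            if j > i:
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                if dx > hx:
                                    dx -= box[0]
                                elif dx < -hx:
                                    dx += box[0]
                                if dy > hy:
                                    dy -= box[1]
                                elif dy < -hy:
                                    dy += box[1]
                                if dz > hz:
                                    dz -= box[2]
                                elif dz < -hz:
                                    dz += box[2]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < rl2:
                                    if ci >= max_neigh:
                                        return neigh, counts, False
                                    neigh[base + ci] = j
                                    ci += 1
                            j = nxt[j]
            counts[i] = ci
    return neigh, counts, True


@njit(cache=True, fastmath=True)
def pair_forces(pos, species, box, eps, rcut2, shift, bond_partner,
                neigh, counts, max_neigh, forces):
    """Nonbonded forces/energy from the half neighbor list.

    Returns (potential_energy, error_code); forces are accumulated in place
    (caller zeroes the array).
    """
    n = pos.shape[0]
    pe = 0.0
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    epsf = eps.ravel()
    rcut2f = rcut2.ravel()
    shiftf = shift.ravel()
    err = 0
    for i in range(n):
        si5 = species[i] * 5
        b0 = bond_partner[i, 0]
        b1 = bond_partner[i, 1]
        xi_ = pos[i, 0]
        yi_ = pos[i, 1]
        zi_ = pos[i, 2]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        base = i * max_neigh
        for k in range(counts[i]):
            j = neigh[base + k]
            if b0 == j or b1 == j:
                continue
            dx = xi_ - pos[j, 0]
            dy = yi_ - pos[j, 1]
            dz = zi_ - pos[j, 2]
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
            r2 = dx * dx + dy * dy + dz * dz
            idx = si5 + species[j]
            if r2 < rcut2f[idx]:
                if r2 < _R2_MIN:
                    err = 3
                    continue
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                inv12 = inv6 * inv6
                e = epsf[idx]
                pe += 4.0 * e * (inv12 - inv6) + shiftf[idx]
                f = 24.0 * e * (2.0 * inv12 - inv6) * inv2
                fdx = f * dx
                fdy = f * dy
                fdz = f * dz
                fx += fdx
                fy += fdy
                fz += fdz
                forces[j, 0] -= fdx
                forces[j, 1] -= fdy
                forces[j, 2] -= fdz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
    return pe, err


@njit(cache=True, fastmath=True)
def bond_forces(pos, box, bonds, forces):
    """FENE + unit-epsilon WCA bond terms.  Returns (energy, error_code)."""
    pe = 0.0
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    kr2 = FENE_K * FENE_R0 * FENE_R0
    r02 = FENE_R0 * FENE_R0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > hx:
            dx -= box[0]
        elif dx < -hx:
            dx += box[0]
        if dy > hy:
            dy -= box[1]
        elif dy < -hy:
            dy += box[1]
        if dz > hz:
            dz -= box[2]
        elif dz < -hz:
            dz += box[2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return pe, 1
        if r2 < _R2_MIN:
            return pe, 3
        x = r2 / r02
        pe += -0.5 * kr2 * np.log(1.0 - x)
        f = -FENE_K / (1.0 - x)  # attractive
        if r2 < _WCA_RC2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            pe += 4.0 * (inv12 - inv6) + 1.0
            f += 24.0 * (2.0 * inv12 - inv6) * inv2
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    return pe, 0


@njit(cache=True)
def _kinetic2(vel, mobile):
    k2 = 0.0
    for i in range(vel.shape[0]):
        if mobile[i]:
            k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    return k2


@njit(cache=True)
def _nh_half(vel, mobile, xi, dt, q, g_t):
    """Half-step Nose-Hoover thermostat update (single chain, two quarter kicks)."""
    k2 = _kinetic2(vel, mobile)
    xi += 0.25 * dt * (k2 - g_t) / q
    s = np.exp(-0.5 * dt * xi)
    for i in range(vel.shape[0]):
        if mobile[i]:
            vel[i, 0] *= s
            vel[i, 1] *= s
            vel[i, 2] *= s
    k2 *= s * s
    xi += 0.25 * dt * (k2 - g_t) / q
    return xi


@njit(cache=True, fastmath=True)
def integrate(pos, vel, species, mobile, box, eps, rcut2, shift,
              bond_partner, bonds, dt, n_steps, step0,
              temperature, tau_t, xi, skin, max_neigh,
              snap_every, snaps, snap_steps,
              log_every, log_rows):
    """Velocity-Verlet / Nose-Hoover loop.  Mutates pos/vel in place.

    snaps: (n_snap_cap, N, 3) float32 buffer, snap_steps int64 buffer;
    log_rows: (n_log_cap, 5) buffer of (step, KE, PE, T, xi).
    Returns (error_code, xi, n_snaps, n_logs, final_pe).
    """
    n = pos.shape[0]
    n_mobile = 0
    for i in range(n):
        if mobile[i]:
            n_mobile += 1
    dof = max(3 * n_mobile - 3, 1)
    g_t = dof * temperature
    use_nh = tau_t > 0.0
    q = g_t * tau_t * tau_t if use_nh else 1.0

    rlist = np.sqrt(np.max(rcut2)) + skin
    half_skin2 = (0.5 * skin) ** 2
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]

    neigh, counts, ok = build_neighbor_list(pos, box, rlist, max_neigh)
    if not ok:
        return 4, xi, 0, 0, 0.0
    pos_ref = pos.copy()

    forces = np.zeros((n, 3))
    pe_p, err = pair_forces(pos, species, box, eps, rcut2, shift,
                            bond_partner, neigh, counts, max_neigh, forces)
    if err != 0:
        return err, xi, 0, 0, 0.0
    pe_b, err = bond_forces(pos, box, bonds, forces)
    if err != 0:
        return err, xi, 0, 0, 0.0
    pe = pe_p + pe_b

    i_snap = 0
    i_log = 0
    for step in range(n_steps):
        if use_nh:
            xi = _nh_half(vel, mobile, xi, dt, q, g_t)
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]

        # wrap + rebuild check
        max_d2 = 0.0
        for i in range(n):
            for k in range(3):
                if pos[i, k] >= box[k]:
                    pos[i, k] -= box[k] * np.floor(pos[i, k] / box[k])
                elif pos[i, k] < 0.0:
                    pos[i, k] -= box[k] * np.floor(pos[i, k] / box[k])
            dx = pos[i, 0] - pos_ref[i, 0]
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > half_skin2:
            neigh, counts, ok = build_neighbor_list(pos, box, rlist, max_neigh)
            if not ok:
                return 4, xi, i_snap, i_log, pe
            pos_ref[:] = pos

        forces[:] = 0.0
        pe_p, err = pair_forces(pos, species, box, eps, rcut2, shift,
                                bond_partner, neigh, counts, max_neigh, forces)
        if err != 0:
            return err, xi, i_snap, i_log, pe
        pe_b, err = bond_forces(pos, box, bonds, forces)
        if err != 0:
            return err, xi, i_snap, i_log, pe
        pe = pe_p + pe_b

        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        if use_nh:
            xi = _nh_half(vel, mobile, xi, dt, q, g_t)

        if not np.isfinite(pe):
            return 2, xi, i_snap, i_log, pe

        gstep = step0 + step + 1
        if snap_every > 0 and gstep % snap_every == 0 and i_snap < snaps.shape[0]:
            for i in range(n):
                snaps[i_snap, i, 0] = pos[i, 0]
                snaps[i_snap, i, 1] = pos[i, 1]
                snaps[i_snap, i, 2] = pos[i, 2]
            snap_steps[i_snap] = gstep
            i_snap += 1
        if log_every > 0 and gstep % log_every == 0 and i_log < log_rows.shape[0]:
            k2 = _kinetic2(vel, mobile)
            log_rows[i_log, 0] = gstep
            log_rows[i_log, 1] = 0.5 * k2
            log_rows[i_log, 2] = pe
            log_rows[i_log, 3] = k2 / dof
            log_rows[i_log, 4] = xi
            i_log += 1

    return 0, xi, i_snap, i_log, pe


@njit(cache=True)
def insert_molecules(mol_sizes, mol_lower, box, zsplit, min_dist,
                     bond_length, max_retries, seed, fixed):
    """Random sequential insertion of molecules into half-slabs.

    ``mol_lower[m]`` selects the z < zsplit half for molecule m (oil), the
    upper half otherwise.  Chains grow bead-by-bead at ``bond_length`` with a
    hard minimum distance to all previously placed beads, including the
    pre-placed ``fixed`` beads (prepended to the returned array).  Returns
    (positions, error_code); error 1 = packing failure.
    """
    np.random.seed(seed)
    nf = fixed.shape[0]
    n = nf
    for m in range(mol_sizes.shape[0]):
        n += mol_sizes[m]
    pos = np.empty((n, 3))
    for i in range(nf):
        pos[i, 0] = fixed[i, 0] - box[0] * np.floor(fixed[i, 0] / box[0])
        pos[i, 1] = fixed[i, 1] - box[1] * np.floor(fixed[i, 1] / box[1])
        pos[i, 2] = fixed[i, 2] - box[2] * np.floor(fixed[i, 2] / box[2])
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    ncx = max(1, int(box[0] / min_dist))
    ncy = max(1, int(box[1] / min_dist))
    ncz = max(1, int(box[2] / min_dist))
    clx = box[0] / ncx
    cly = box[1] / ncy
    clz = box[2] / ncz
    head = -np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    d2min = min_dist * min_dist

    for i in range(nf):
        cx = int(pos[i, 0] / clx) % ncx
        cy = int(pos[i, 1] / cly) % ncy
        cz = int(pos[i, 2] / clz) % ncz
        c = (cz * ncy + cy) * ncx + cx
        nxt[i] = head[c]
        head[c] = i

    idx = nf
    for m in range(mol_sizes.shape[0]):
        if mol_lower[m]:
            zlo, zhi = 0.0, zsplit
        else:
            zlo, zhi = zsplit, box[2]
        placed = 0
        tries = 0
        while placed < mol_sizes[m]:
            if placed == 0:
                px = np.random.random() * box[0]
                py = np.random.random() * box[1]
                pz = zlo + np.random.random() * (zhi - zlo)
            else:
                vx = np.random.normal()
                vy = np.random.normal()
                vz = np.random.normal()
                vn = np.sqrt(vx * vx + vy * vy + vz * vz)
                if vn < 1e-12:
                    continue
                px = pos[idx - 1, 0] + bond_length * vx / vn
                py = pos[idx - 1, 1] + bond_length * vy / vn
                pz = pos[idx - 1, 2] + bond_length * vz / vn
                px -= box[0] * np.floor(px / box[0])
                py -= box[1] * np.floor(py / box[1])
                if pz < zlo or pz >= zhi:
                    tries += 1
                    if tries > max_retries:
                        return pos, 1
                    continue
            # overlap check over the 27 surrounding cells
            cx = int(px / clx) % ncx
            cy = int(py / cly) % ncy
            cz = int(pz / clz) % ncz
            ok = True
            for ox in range(-1, 2):
                if not ok:
                    break
                for oy in range(-1, 2):
                    if not ok:
                        break
                    for oz in range(-1, 2):
                        c = (((cz + oz) % ncz) * ncy + (cy + oy) % ncy) * ncx \
                            + (cx + ox) % ncx
                        j = head[c]
                        while j >= 0:
                            dx = px - pos[j, 0]
                            dy = py - pos[j, 1]
                            dz = pz - pos[j, 2]
                            if dx > hx:
                                dx -= box[0]
                            elif dx < -hx:
                                dx += box[0]
                            if dy > hy:
                                dy -= box[1]
                            elif dy < -hy:
                                dy += box[1]
                            if dz > hz:
                                dz -= box[2]
                            elif dz < -hz:
                                dz += box[2]
                            if dx * dx + dy * dy + dz * dz < d2min:
                                ok = False
                                break
                            j = nxt[j]
                        if not ok:
                            break
            if ok:
                pos[idx, 0] = px
                pos[idx, 1] = py
                pos[idx, 2] = pz
                c = (cz * ncy + cy) * ncx + cx
                nxt[idx] = head[c]
                head[c] = idx
                idx += 1
                placed += 1
                tries = 0
            else:
                tries += 1
                if tries > max_retries:
                    return pos, 1
    return pos, 0
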