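"""Numba-compiled hot loops: neighbor search, force evaluation, integration.

Mirrors :mod:`memligkin.potentials` exactly; the test suite asserts that
cell-list forces equal the brute-force reference to machine precision.
All kernels are sequential and use fixed summation order, so trajectories
are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

RC_WCA_FACTOR = 2.0 ** (1.0 / 6.0)

# energy term slots
E_REP, E_FENE, E_SPRING, E_ATTR, E_BEND, E_BIND, E_RESTR = range(7)

# status codes from compute_forces
STATUS_OK = 0
STATUS_FENE_OVERSTRETCH = 1
STATUS_NONFINITE = 2


@njit(cache=True, inline="always")
def _min_image(dx, L, periodic):
    if periodic and L > 0.0:
        dx -= L * math.floor(dx / L + 0.5)
    return dx


@njit(cache=True, inline="always")
def _mi_cmp(d, L, hL):
    # comparison-based minimum image; valid for wrapped coordinates
    if d > hL:
        d -= L
    elif d < -hL:
        d += L
    return d


@njit(cache=True, fastmath=True)
def build_pair_list(pos, box_l, periodic, hydrophobic,
                    cut_short, cut_long, skin, capacity):
    """Verlet pair list via linked cells with per-pair-type list cutoffs.

    ``cut_long`` applies when both beads are hydrophobic (tail cohesion
    range), ``cut_short`` otherwise (WCA range).  Falls back to an
    all-pairs scan when the box is too small for 3 cells per axis.
    Returns (pairs (M,2) int32, count); count > capacity signals the caller
    to retry with a larger buffer.
    """
    n = pos.shape[0]
    rlist_long = cut_long + skin
    rlist_short = cut_short + skin
    r2_long = rlist_long * rlist_long
    r2_short = rlist_short * rlist_short
    pairs = np.empty((capacity, 2), dtype=np.int32)
    lx = box_l[0]
    ly = box_l[1]
    lz = box_l[2]
    hx = 0.5 * lx if periodic[0] else 1e300
    hy = 0.5 * ly if periodic[1] else 1e300
    hz = 0.5 * lz if periodic[2] else 1e300

    ncx = int(box_l[0] / rlist_long)
    ncy = int(box_l[1] / rlist_long)
    ncz = int(box_l[2] / rlist_long)
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3 and n > 64

    if not use_cells:
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _mi_cmp(pos[j, 0] - pos[i, 0], lx, hx)
                dy = _mi_cmp(pos[j, 1] - pos[i, 1], ly, hy)
                dz = _mi_cmp(pos[j, 2] - pos[i, 2], lz, hz)
                r2 = dx * dx + dy * dy + dz * dz
                lim = r2_long if (hydrophobic[i] and hydrophobic[j]) else r2_short
                if r2 < lim:
                    if k < capacity:
                        pairs[k, 0] = i
                        pairs[k, 1] = j
                    k += 1
        return pairs, k

    ncell = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int32)
    count = np.zeros(ncell, dtype=np.int32)
    for i in range(n):
        cx = int(pos[i, 0] / box_l[0] * ncx)
        cy = int(pos[i, 1] / box_l[1] * ncy)
        cz = int(pos[i, 2] / box_l[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c] += 1
    start = np.zeros(ncell + 1, dtype=np.int32)
    for c in range(ncell):
        start[c + 1] = start[c] + count[c]
    order = np.empty(n, dtype=np.int32)
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # half stencil: self cell (i<j) + 13 neighbor cells
    offs = np.array([
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ], dtype=np.int64)

    k = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                # within-cell pairs
                for ia in range(start[c], start[c + 1]):
                    i = order[ia]
                    for jb in range(ia + 1, start[c + 1]):
                        j = order[jb]
                        dx = _mi_cmp(pos[j, 0] - pos[i, 0], lx, hx)
                        dy = _mi_cmp(pos[j, 1] - pos[i, 1], ly, hy)
                        dz = _mi_cmp(pos[j, 2] - pos[i, 2], lz, hz)
                        r2 = dx * dx + dy * dy + dz * dz
                        lim = r2_long if (hydrophobic[i] and hydrophobic[j]) else r2_short
                        if r2 < lim:
                            if k < capacity:
                                pairs[k, 0] = i
                                pairs[k, 1] = j
                            k += 1
                # neighbor-cell pairs
                for o in range(13):
                    nx = cx + offs[o, 0]
                    ny = cy + offs[o, 1]
                    nz = cz + offs[o, 2]
                    if periodic[0]:
                        nx = nx % ncx
                    elif nx < 0 or nx >= ncx:
                        continue
                    if periodic[1]:
                        ny = ny % ncy
                    elif ny < 0 or ny >= ncy:
                        continue
                    if periodic[2]:
                        nz = nz % ncz
                    elif nz < 0 or nz >= ncz:
                        continue
                    c2 = (nx * ncy + ny) * ncz + nz
                    for ia in range(start[c], start[c + 1]):
                        i = order[ia]
                        for jb in range(start[c2], start[c2 + 1]):
                            j = order[jb]
                            dx = _mi_cmp(pos[j, 0] - pos[i, 0], lx, hx)
                            dy = _mi_cmp(pos[j, 1] - pos[i, 1], ly, hy)
                            dz = _mi_cmp(pos[j, 2] - pos[i, 2], lz, hz)
                            r2 = dx * dx + dy * dy + dz * dz
                            lim = r2_long if (hydrophobic[i] and hydrophobic[j]) else r2_short
                            if r2 < lim:
                                if k < capacity:
                                    pairs[k, 0] = i
                                    pairs[k, 1] = j
                                k += 1
    return pairs, k


@njit(cache=True)
def partition_pairs(pairs, n_pairs, hydrophobic, is_tmd):
    """Split the Verlet list into cohesion-carrying pairs (tail-tail and
    tail-TMD; never TMD-TMD, which would make receptors cluster) and the
    WCA-only rest; lets the force loop hoist all pair constants."""
    n_h = 0
    for m in range(n_pairs):
        i = pairs[m, 0]
        j = pairs[m, 1]
        if (hydrophobic[i] and hydrophobic[j]
                and not (is_tmd[i] and is_tmd[j])):
            n_h += 1
    pairs_h = np.empty((n_h, 2), dtype=np.int32)
    pairs_o = np.empty((n_pairs - n_h, 2), dtype=np.int32)
    kh = 0
    ko = 0
    for m in range(n_pairs):
        i = pairs[m, 0]
        j = pairs[m, 1]
        if (hydrophobic[i] and hydrophobic[j]
                and not (is_tmd[i] and is_tmd[j])):
            pairs_h[kh, 0] = i
            pairs_h[kh, 1] = j
            kh += 1
        else:
            pairs_o[ko, 0] = i
            pairs_o[ko, 1] = j
            ko += 1
    return pairs_h, pairs_o


@njit(cache=True, fastmath=True)
def compute_forces(pos, pairs_h, pairs_o, box_l, periodic,
                   sigma_tail, sigma_other,
                   eps_rep, attr_eps, attr_wc,
                   bond_ij, bond_kind,
                   fene_k, fene_rmax, spring_k, spring_r0,
                   bond_k, bond_r0, tmd_k, tmd_r0,
                   angle_ijk, angle_k, angle_th0,
                   sites_r, sites_l, axis_r, axis_l, partner_r,
                   eps_bind, bind_rcut,
                   restrained, support_k, restraint_z0,
                   forces, energies, virial):
    """Fill forces (N,3), energies (7,), virial (3,); returns a status code."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for t in range(7):
        energies[t] = 0.0
    virial[0] = 0.0
    virial[1] = 0.0
    virial[2] = 0.0

    # comparison-based minimum image (positions are kept wrapped)
    lx = box_l[0]
    ly = box_l[1]
    lz = box_l[2]
    hx = 0.5 * lx if periodic[0] else 1e300
    hy = 0.5 * ly if periodic[1] else 1e300
    hz = 0.5 * lz if periodic[2] else 1e300

    # hydrophobic pairs: WCA (d = sigma_tail) + cos^2-tapered cohesion
    d = sigma_tail
    d2 = d * d
    rc = RC_WCA_FACTOR * d
    rc2 = rc * rc
    rc_out = rc + attr_wc
    rc_out2 = rc_out * rc_out
    taper = math.pi / (2.0 * attr_wc)
    for m in range(pairs_h.shape[0]):
        i = pairs_h[m, 0]
        j = pairs_h[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        if dx > hx:
            dx -= lx
        elif dx < -hx:
            dx += lx
        dy = pos[j, 1] - pos[i, 1]
        if dy > hy:
            dy -= ly
        elif dy < -hy:
            dy += ly
        dz = pos[j, 2] - pos[i, 2]
        if dz > hz:
            dz -= lz
        elif dz < -hz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_out2:
            continue
        if r2 < rc2:
            inv_r2 = 1.0 / r2
            s2 = d2 * inv_r2
            s6 = s2 * s2 * s2
            energies[E_REP] += 4.0 * eps_rep * (s6 * s6 - s6) + eps_rep
            energies[E_ATTR] += -attr_eps
            fscale = 24.0 * eps_rep * (2.0 * s6 * s6 - s6) * inv_r2
        else:
            r = math.sqrt(r2)
            arg = taper * (r - rc)
            c = math.cos(arg)
            energies[E_ATTR] += -attr_eps * c * c
            fscale = -attr_eps * taper * math.sin(2.0 * arg) / r
        fx = fscale * dx
        fy = fscale * dy
        fz = fscale * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz

    # all other pairs: WCA only (d = sigma_other)
    d = sigma_other
    d2 = d * d
    rc2 = RC_WCA_FACTOR * RC_WCA_FACTOR * d2
    for m in range(pairs_o.shape[0]):
        i = pairs_o[m, 0]
        j = pairs_o[m, 1]
        dx = pos[j, 0] - pos[i, 0]
        if dx > hx:
            dx -= lx
        elif dx < -hx:
            dx += lx
        dy = pos[j, 1] - pos[i, 1]
        if dy > hy:
            dy -= ly
        elif dy < -hy:
            dy += ly
        dz = pos[j, 2] - pos[i, 2]
        if dz > hz:
            dz -= lz
        elif dz < -hz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        inv_r2 = 1.0 / r2
        s2 = d2 * inv_r2
        s6 = s2 * s2 * s2
        energies[E_REP] += 4.0 * eps_rep * (s6 * s6 - s6) + eps_rep
        fscale = 24.0 * eps_rep * (2.0 * s6 * s6 - s6) * inv_r2
        fx = fscale * dx
        fy = fscale * dy
        fz = fscale * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz

    # bonds
    for m in range(bond_ij.shape[0]):
        i = bond_ij[m, 0]
        j = bond_ij[m, 1]
        kind = bond_kind[m]
        dx = _min_image(pos[j, 0] - pos[i, 0], box_l[0], periodic[0])
        dy = _min_image(pos[j, 1] - pos[i, 1], box_l[1], periodic[1])
        dz = _min_image(pos[j, 2] - pos[i, 2], box_l[2], periodic[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if kind == 0:  # FENE
            if r >= fene_rmax:
                return STATUS_FENE_OVERSTRETCH
            x = (r / fene_rmax) * (r / fene_rmax)
            energies[E_FENE] += -0.5 * fene_k * fene_rmax * fene_rmax * math.log(1.0 - x)
            dedr = fene_k * r / (1.0 - x)
        elif kind == 1:  # lipid straightening spring
            energies[E_SPRING] += 0.5 * spring_k * (r - spring_r0) ** 2
            dedr = spring_k * (r - spring_r0)
        elif kind == 2:  # protein backbone
            energies[E_SPRING] += 0.5 * bond_k * (r - bond_r0) ** 2
            dedr = bond_k * (r - bond_r0)
        else:  # TMD rod
            energies[E_SPRING] += 0.5 * tmd_k * (r - tmd_r0) ** 2
            dedr = tmd_k * (r - tmd_r0)
        if r > 0.0:
            fx = -dedr * dx / r
            fy = -dedr * dy / r
            fz = -dedr * dz / r
            forces[j, 0] += fx
            forces[j, 1] += fy
            forces[j, 2] += fz
            forces[i, 0] -= fx
            forces[i, 1] -= fy
            forces[i, 2] -= fz
            virial[0] += fx * dx
            virial[1] += fy * dy
            virial[2] += fz * dz

    # angles
    for m in range(angle_ijk.shape[0]):
        i = angle_ijk[m, 0]
        j = angle_ijk[m, 1]
        k = angle_ijk[m, 2]
        kb = angle_k[m]
        th0 = angle_th0[m]
        ax = _min_image(pos[i, 0] - pos[j, 0], box_l[0], periodic[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], box_l[1], periodic[1])
        az = _min_image(pos[i, 2] - pos[j, 2], box_l[2], periodic[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], box_l[0], periodic[0])
        by = _min_image(pos[k, 1] - pos[j, 1], box_l[1], periodic[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], box_l[2], periodic[2])
        na = math.sqrt(ax * ax + ay * ay + az * az)
        nb = math.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (na * nb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        energies[E_BEND] += kb * (1.0 - math.cos(theta - th0))
        st = math.sqrt(max(1.0 - ct * ct, 1e-16))
        dedcos = -kb * math.cos(th0) + kb * ct * math.sin(th0) / st
        gix = dedcos * (bx / (na * nb) - ct * ax / (na * na))
        giy = dedcos * (by / (na * nb) - ct * ay / (na * na))
        giz = dedcos * (bz / (na * nb) - ct * az / (na * na))
        gkx = dedcos * (ax / (na * nb) - ct * bx / (nb * nb))
        gky = dedcos * (ay / (na * nb) - ct * by / (nb * nb))
        gkz = dedcos * (az / (na * nb) - ct * bz / (nb * nb))
        forces[i, 0] -= gix
        forces[i, 1] -= giy
        forces[i, 2] -= giz
        forces[k, 0] -= gkx
        forces[k, 1] -= gky
        forces[k, 2] -= gkz
        forces[j, 0] += gix + gkx
        forces[j, 1] += giy + gky
        forces[j, 2] += giz + gkz
        virial[0] += -gix * ax - gkx * bx
        virial[1] += -giy * ay - gky * by
        virial[2] += -giz * az - gkz * bz

    # specific site-site binding (active 1:1 pairs only)
    for ir in range(partner_r.shape[0]):
        jl = partner_r[ir]
        if jl < 0:
            continue
        i_ar = axis_r[ir]
        i_sr = sites_r[ir]
        i_sl = sites_l[jl]
        i_al = axis_l[jl]
        axx = _min_image(pos[i_sr, 0] - pos[i_ar, 0], box_l[0], periodic[0])
        axy = _min_image(pos[i_sr, 1] - pos[i_ar, 1], box_l[1], periodic[1])
        axz = _min_image(pos[i_sr, 2] - pos[i_ar, 2], box_l[2], periodic[2])
        bxx = _min_image(pos[i_sl, 0] - pos[i_al, 0], box_l[0], periodic[0])
        bxy = _min_image(pos[i_sl, 1] - pos[i_al, 1], box_l[1], periodic[1])
        bxz = _min_image(pos[i_sl, 2] - pos[i_al, 2], box_l[2], periodic[2])
        dxx = _min_image(pos[i_sl, 0] - pos[i_sr, 0], box_l[0], periodic[0])
        dxy = _min_image(pos[i_sl, 1] - pos[i_sr, 1], box_l[1], periodic[1])
        dxz = _min_image(pos[i_sl, 2] - pos[i_sr, 2], box_l[2], periodic[2])
        r = math.sqrt(dxx * dxx + dxy * dxy + dxz * dxz)
        if r <= 0.0 or r >= bind_rcut:
            continue
        na = math.sqrt(axx * axx + axy * axy + axz * axz)
        nb = math.sqrt(bxx * bxx + bxy * bxy + bxz * bxz)
        c1 = (axx * dxx + axy * dxy + axz * dxz) / (na * r)
        c2 = -(bxx * dxx + bxy * dxy + bxz * dxz) / (nb * r)
        if c1 <= 0.0 or c2 <= 0.0:
            continue
        u = 1.0 - (r / bind_rcut) ** 2
        g = u * u
        energies[E_BIND] += -eps_bind * c1 * c1 * c2 * c2 * g
        dedc1 = -2.0 * eps_bind * c1 * c2 * c2 * g
        dedc2 = -2.0 * eps_bind * c1 * c1 * c2 * g
        dedr = -eps_bind * c1 * c1 * c2 * c2 * 2.0 * u * (-2.0 * r / (bind_rcut * bind_rcut))
        # gradients wrt a, b, d
        ga_x = dedc1 * (dxx / (na * r) - c1 * axx / (na * na))
        ga_y = dedc1 * (dxy / (na * r) - c1 * axy / (na * na))
        ga_z = dedc1 * (dxz / (na * r) - c1 * axz / (na * na))
        gb_x = dedc2 * (-dxx / (nb * r) - c2 * bxx / (nb * nb))
        gb_y = dedc2 * (-dxy / (nb * r) - c2 * bxy / (nb * nb))
        gb_z = dedc2 * (-dxz / (nb * r) - c2 * bxz / (nb * nb))
        gd_x = dedc1 * (axx / (na * r) - c1 * dxx / (r * r)) \
            + dedc2 * (-bxx / (nb * r) - c2 * dxx / (r * r)) + dedr * dxx / r
        gd_y = dedc1 * (axy / (na * r) - c1 * dxy / (r * r)) \
            + dedc2 * (-bxy / (nb * r) - c2 * dxy / (r * r)) + dedr * dxy / r
        gd_z = dedc1 * (axz / (na * r) - c1 * dxz / (r * r)) \
            + dedc2 * (-bxz / (nb * r) - c2 * dxz / (r * r)) + dedr * dxz / r
        # forces on (axis_r, site_r, site_l, axis_l)
        f_ar = (ga_x, ga_y, ga_z)
        forces[i_ar, 0] += f_ar[0]
        forces[i_ar, 1] += f_ar[1]
        forces[i_ar, 2] += f_ar[2]
        forces[i_sr, 0] += -ga_x + gd_x
        forces[i_sr, 1] += -ga_y + gd_y
        forces[i_sr, 2] += -ga_z + gd_z
        forces[i_sl, 0] += -(gb_x + gd_x)
        forces[i_sl, 1] += -(gb_y + gd_y)
        forces[i_sl, 2] += -(gb_z + gd_z)
        forces[i_al, 0] += gb_x
        forces[i_al, 1] += gb_y
        forces[i_al, 2] += gb_z
        # virial: f . (x - x_site_r) for each involved bead
        # axis_r at -a, site_l at +d, axis_l at d - b (relative to site_r)
        virial[0] += f_ar[0] * (-axx) + (-(gb_x + gd_x)) * dxx + gb_x * (dxx - bxx)
        virial[1] += f_ar[1] * (-axy) + (-(gb_y + gd_y)) * dxy + gb_y * (dxy - bxy)
        virial[2] += f_ar[2] * (-axz) + (-(gb_z + gd_z)) * dxz + gb_z * (dxz - bxz)

    # plane restraint
    for m in range(restrained.shape[0]):
        i = restrained[m]
        dz = pos[i, 2] - restraint_z0
        energies[E_RESTR] += 0.5 * support_k * dz * dz
        forces[i, 2] -= support_k * dz
        virial[2] += -support_k * dz * dz

    return STATUS_OK


@njit(cache=True)
def update_binding_pairs(pos, box_l, periodic,
                         sites_r, sites_l, axis_r, axis_l,
                         partner_r, partner_l, eps_bind, bind_rcut):
    """In-place 1:1 registry update: dissolve out-of-range pairs, then
    greedily assign free sites to the energy-minimizing candidate."""
    n_r = sites_r.shape[0]
    n_l = sites_l.shape[0]
    # dissolve
    for i in range(n_r):
        j = partner_r[i]
        if j < 0:
            continue
        dx = _min_image(pos[sites_l[j], 0] - pos[sites_r[i], 0], box_l[0], periodic[0])
        dy = _min_image(pos[sites_l[j], 1] - pos[sites_r[i], 1], box_l[1], periodic[1])
        dz = _min_image(pos[sites_l[j], 2] - pos[sites_r[i], 2], box_l[2], periodic[2])
        if dx * dx + dy * dy + dz * dz >= bind_rcut * bind_rcut:
            partner_r[i] = -1
            partner_l[j] = -1
    # candidate energies for free-free pairs
    n_cand = 0
    cand_e = np.empty(n_r * n_l, dtype=np.float64)
    cand_i = np.empty(n_r * n_l, dtype=np.int64)
    cand_j = np.empty(n_r * n_l, dtype=np.int64)
    for i in range(n_r):
        if partner_r[i] >= 0:
            continue
        for j in range(n_l):
            if partner_l[j] >= 0:
                continue
            dxx = _min_image(pos[sites_l[j], 0] - pos[sites_r[i], 0], box_l[0], periodic[0])
            dxy = _min_image(pos[sites_l[j], 1] - pos[sites_r[i], 1], box_l[1], periodic[1])
            dxz = _min_image(pos[sites_l[j], 2] - pos[sites_r[i], 2], box_l[2], periodic[2])
            r2 = dxx * dxx + dxy * dxy + dxz * dxz
            if r2 >= bind_rcut * bind_rcut or r2 <= 0.0:
                continue
            r = math.sqrt(r2)
            axx = _min_image(pos[sites_r[i], 0] - pos[axis_r[i], 0], box_l[0], periodic[0])
            axy = _min_image(pos[sites_r[i], 1] - pos[axis_r[i], 1], box_l[1], periodic[1])
            axz = _min_image(pos[sites_r[i], 2] - pos[axis_r[i], 2], box_l[2], periodic[2])
            bxx = _min_image(pos[sites_l[j], 0] - pos[axis_l[j], 0], box_l[0], periodic[0])
            bxy = _min_image(pos[sites_l[j], 1] - pos[axis_l[j], 1], box_l[1], periodic[1])
            bxz = _min_image(pos[sites_l[j], 2] - pos[axis_l[j], 2], box_l[2], periodic[2])
            na = math.sqrt(axx * axx + axy * axy + axz * axz)
            nb = math.sqrt(bxx * bxx + bxy * bxy + bxz * bxz)
            c1 = (axx * dxx + axy * dxy + axz * dxz) / (na * r)
            c2 = -(bxx * dxx + bxy * dxy + bxz * dxz) / (nb * r)
            e = 0.0
            if c1 > 0.0 and c2 > 0.0:
                u = 1.0 - (r / bind_rcut) ** 2
                e = -eps_bind * c1 * c1 * c2 * c2 * u * u
            cand_e[n_cand] = e
            cand_i[n_cand] = i
            cand_j[n_cand] = j
            n_cand += 1
    # greedy: repeatedly take the lowest-energy unconsumed candidate
    used = np.zeros(n_cand, dtype=np.uint8)
    for _ in range(n_cand):
        best = -1
        best_e = 1e300
        for m in range(n_cand):
            if used[m]:
                continue
            if cand_e[m] < best_e:
                best_e = cand_e[m]
                best = m
        if best < 0:
            break
        used[best] = 1
        i = cand_i[best]
        j = cand_j[best]
        if partner_r[i] < 0 and partner_l[j] < 0:
            partner_r[i] = j
            partner_l[j] = i


@njit(cache=True)
def baoab_bao_a(pos, vel, forces, disp, dt, c1, c2, noise, box_l, periodic):
    """First part of a BAOAB step: B(dt/2), A(dt/2), O, A(dt/2).

    Updates positions in place (wrapped), accumulates unwrapped displacement
    since the last neighbor build in ``disp`` and returns the maximum squared
    displacement (rebuild trigger).
    """
    n = pos.shape[0]
    half = 0.5 * dt
    max_d2 = 0.0
    for i in range(n):
        for a in range(3):
            v = vel[i, a] + half * forces[i, a]
            x_old = pos[i, a]
            x = x_old + half * v
            v = c1 * v + c2 * noise[i, a]
            x = x + half * v
            vel[i, a] = v
            disp[i, a] += x - x_old
            if periodic[a]:
                L = box_l[a]
                x -= L * math.floor(x / L)
            pos[i, a] = x
        d2 = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
        if d2 > max_d2:
            max_d2 = d2
    return max_d2


@njit(cache=True)
def kick(vel, forces, half_dt):
    n = vel.shape[0]
    for i in range(n):
        vel[i, 0] += half_dt * forces[i, 0]
        vel[i, 1] += half_dt * forces[i, 1]
        vel[i, 2] += half_dt * forces[i, 2]


@njit(cache=True)
def kinetic_tensor(vel):
    """Diagonal of the kinetic-energy tensor sum(m v_a^2), m = 1."""
    out = np.zeros(3)
    for i in range(vel.shape[0]):
        out[0] += vel[i, 0] * vel[i, 0]
        out[1] += vel[i, 1] * vel[i, 1]
        out[2] += vel[i, 2] * vel[i, 2]
    return out


@njit(cache=True)
def scale_lateral(pos, box_l, scale):
    """Affine x-y rescaling of coordinates and box (zero-tension control)."""
    for i in range(pos.shape[0]):
        pos[i, 0] *= scale
        pos[i, 1] *= scale
    box_l[0] *= scale
    box_l[1] *= scale
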