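"""Numba force kernels: FENE bonds, Kratky-Porod angles, WCA pairs.

All quantities are in reduced units (sigma = kT = mass = 1).  The pair term
uses a linked-cell list when the box holds at least 3 cells per side and
falls back to an O(N^2) loop otherwise.  Force capping (for push-off
relaxation) replaces the WCA branch below ``r_cap`` by a linear potential of
constant slope ``f_cap``; pass ``f_cap <= 0`` for full WCA.

The kernel returns an error flag (1 = FENE overstretch) instead of raising,
so callers can produce a diagnostic with context.
"""

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=False)
def _min_image(d, box):
    if box > 0.0:
        return d - box * np.round(d / box)
    return d


@njit(cache=True)
def _pair_fe(r2, eps, f_cap, r_cap, u_cap):
    """WCA force/r and energy at squared distance r2 (< cutoff^2)."""
    r = np.sqrt(r2)
    if f_cap > 0.0 and r < r_cap:
        # capped linear branch for push-off
        u = u_cap + f_cap * (r_cap - r)
        return f_cap / r, u
    inv2 = 1.0 / r2
    inv6 = inv2 * inv2 * inv2
    inv12 = inv6 * inv6
    u = 4.0 * eps * (inv12 - inv6) + eps
    f_over_r = 24.0 * eps * (2.0 * inv12 - inv6) * inv2
    return f_over_r, u


@njit(cache=True)
def compute_forces(
    pos,            # (N, 3) float64
    chain_id,       # (N,) int64
    bonds,          # (B, 2) int64
    angles,         # (A, 3) int64
    box,            # float; <= 0 disables periodicity
    fene_k, fene_r0, bend_k, eps,
    f_cap, r_cap, u_cap,
):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    e_fene = 0.0
    e_bend = 0.0
    e_lj_intra = 0.0
    e_lj_inter = 0.0
    err = 0

    r0_sq = fene_r0 * fene_r0

    # --- FENE bonds -------------------------------------------------------
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[j, 0] - pos[i, 0], box)
        dy = _min_image(pos[j, 1] - pos[i, 1], box)
        dz = _min_image(pos[j, 2] - pos[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r0_sq:
            err = 1
            continue
        e_fene += -0.5 * fene_k * r0_sq * np.log(1.0 - r2 / r0_sq)
        fmag_over_r = -fene_k / (1.0 - r2 / r0_sq)  # attractive toward bond
        fx = fmag_over_r * dx
        fy = fmag_over_r * dy
        fz = fmag_over_r * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz

    # --- Kratky-Porod angles ---------------------------------------------
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = _min_image(pos[j, 0] - pos[i, 0], box)
        b1y = _min_image(pos[j, 1] - pos[i, 1], box)
        b1z = _min_image(pos[j, 2] - pos[i, 2], box)
        b2x = _min_image(pos[k, 0] - pos[j, 0], box)
        b2y = _min_image(pos[k, 1] - pos[j, 1], box)
        b2z = _min_image(pos[k, 2] - pos[j, 2], box)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            continue
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        ct = dot / (n1 * n2)
        e_bend += bend_k * (1.0 - ct)
        # d(cos)/db1 and d(cos)/db2
        inv12 = 1.0 / (n1 * n2)
        c1 = ct / (n1 * n1)
        c2 = ct / (n2 * n2)
        d1x = b2x * inv12 - c1 * b1x
        d1y = b2y * inv12 - c1 * b1y
        d1z = b2z * inv12 - c1 * b1z
        d2x = b1x * inv12 - c2 * b2x
        d2y = b1y * inv12 - c2 * b2y
        d2z = b1z * inv12 - c2 * b2z
        # F_i = -k * dcos/db1 ; F_k = +k * dcos/db2 ; F_j balances
        forces[i, 0] -= bend_k * d1x
        forces[i, 1] -= bend_k * d1y
        forces[i, 2] -= bend_k * d1z
        forces[k, 0] += bend_k * d2x
        forces[k, 1] += bend_k * d2y
        forces[k, 2] += bend_k * d2z
        forces[j, 0] += bend_k * (d1x - d2x)
        forces[j, 1] += bend_k * (d1y - d2y)
        forces[j, 2] += bend_k * (d1z - d2z)

    # --- WCA pairs --------------------------------------------------------
    cut = WCA_CUT
    cut2 = cut * cut
    use_cells = box > 0.0 and box / cut >= 3.0 and n > 32
    if use_cells:
        ncell = int(box / cut)
        if ncell > 40:
            ncell = 40
        cs = box / ncell
        head = -np.ones(ncell * ncell * ncell, dtype=np.int64)
        nxt = -np.ones(n, dtype=np.int64)
        cix = np.empty(n, dtype=np.int64)
        ciy = np.empty(n, dtype=np.int64)
        ciz = np.empty(n, dtype=np.int64)
        for i in range(n):
            x = pos[i, 0] - box * np.floor(pos[i, 0] / box)
            y = pos[i, 1] - box * np.floor(pos[i, 1] / box)
            z = pos[i, 2] - box * np.floor(pos[i, 2] / box)
            ix = int(x / cs)
            iy = int(y / cs)
            iz = int(z / cs)
            if ix >= ncell:
                ix = ncell - 1
            if iy >= ncell:
                iy = ncell - 1
            if iz >= ncell:
                iz = ncell - 1
            cix[i] = ix
            ciy[i] = iy
            ciz[i] = iz
            c = (ix * ncell + iy) * ncell + iz
            nxt[i] = head[c]
            head[c] = i
        for ix in range(ncell):
            for iy in range(ncell):
                for iz in range(ncell):
                    c = (ix * ncell + iy) * ncell + iz
                    i = head[c]
                    while i >= 0:
                        # same-cell pairs (j later in list)
                        j = nxt[i]
                        while j >= 0:
                            _acc = _pair_accumulate(
                                pos, chain_id, forces, i, j, box, cut2, eps,
                                f_cap, r_cap, u_cap)
                            e_lj_intra += _acc[0]
                            e_lj_inter += _acc[1]
                            j = nxt[j]
                        # half neighbour cells
                        for noff in range(13):
                            ox = _HALF_OFFSETS[noff, 0]
                            oy = _HALF_OFFSETS[noff, 1]
                            oz = _HALF_OFFSETS[noff, 2]
                            jx = (ix + ox) % ncell
                            jy = (iy + oy) % ncell
                            jz = (iz + oz) % ncell
                            c2i = (jx * ncell + jy) * ncell + jz
                            j = head[c2i]
                            while j >= 0:
                                _acc = _pair_accumulate(
                                    pos, chain_id, forces, i, j, box, cut2,
                                    eps, f_cap, r_cap, u_cap)
                                e_lj_intra += _acc[0]
                                e_lj_inter += _acc[1]
                                j = nxt[j]
                        i = nxt[i]
    else:
        for i in range(n - 1):
            for j in range(i + 1, n):
                _acc = _pair_accumulate(
                    pos, chain_id, forces, i, j, box, cut2, eps,
                    f_cap, r_cap, u_cap)
                e_lj_intra += _acc[0]
                e_lj_inter += _acc[1]

    return forces, e_fene, e_bend, e_lj_intra, e_lj_inter, err


_HALF_OFFSETS = np.array(
    [
        (1, 0, 0), (1, 1, 0), (0, 1, 0), (-1, 1, 0),
        (1, 0, 1), (1, 1, 1), (0, 1, 1), (-1, 1, 1),
        (1, 0, -1), (1, 1, -1), (0, 1, -1), (-1, 1, -1),
        (0, 0, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _pair_accumulate(pos, chain_id, forces, i, j, box, cut2, eps,
                     f_cap, r_cap, u_cap):
    dx = _min_image(pos[j, 0] - pos[i, 0], box)
    dy = _min_image(pos[j, 1] - pos[i, 1], box)
    dz = _min_image(pos[j, 2] - pos[i, 2], box)
    r2 = dx * dx + dy * dy + dz * dz
    e_intra = 0.0
    e_inter = 0.0
    if r2 < cut2 and r2 > 0.0:
        f_over_r, u = _pair_fe(r2, eps, f_cap, r_cap, u_cap)
        if chain_id[i] == chain_id[j]:
            e_intra = u
        else:
            e_inter = u
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
    return e_intra, e_inter
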