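"""Low-level numba kernels for the dynamically triangulated vesicle sampler.

Mesh state lives in flat arrays so the Monte Carlo inner loop compiles to
machine code:

``pos``      (cap, 3) float64   vertex positions (units of the tether length l0)
``nbr``      (cap, MAXDEG) int32  one-ring neighbour ids in cyclic order,
                                  counter-clockwise viewed from outside
``deg``      (cap,) int32       vertex degrees (0 for dead slots)
``vlist``    (cap,) int32       compact list of alive vertex ids
``vindex``   (cap,) int32       position of each id in vlist (-1 if dead)
``d4list``   (cap,) int32       compact list of alive degree-4 vertices
``d4index``  (cap,) int32       inverse of d4list
``freelist`` (cap,) int32       stack of reusable dead vertex ids
``eb``       (cap,) float64     cached per-vertex bending energy
``sc_i``     int64[4]           [nv, n4, nfree, nmin]
``sc_f``     float64[4]         [E_bend, E_area, total area, enclosed volume]

Faces are implicit: for every vertex ``i`` and consecutive ring pair
``(j, k)``, ``(i, j, k)`` is an outward-oriented face.  Sphere topology is
preserved by construction, so the edge and face counts follow from the
vertex count alone (E = 3V - 6, F = 2V - 4).

The discrete bending energy is the cotangent-Laplacian (Itzykson) form
with barycentric vertex areas; the tether is a hard square well and the
area term is harmonic per face.  All energies are in units of kBT.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scalar-state indices
NV, N4, NFREE, NMIN = 0, 1, 2, 3
EBEND, EAREA, AREA, VOL = 0, 1, 2, 3

# move kinds / result codes
TRANSLATE, FLIP, INSERT, REMOVE = 0, 1, 2, 3
ACCEPTED, REJECTED, INVALID = 1, 0, -1

BIG_ENERGY = 1.0e30


# ---------------------------------------------------------------------------
# ring utilities
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _ring_find(nbr, deg, i, j):
    for t in range(deg[i]):
        if nbr[i, t] == j:
            return t
    return -1


@njit(cache=True, inline="always")
def _adjacent(nbr, deg, i, j):
    return _ring_find(nbr, deg, i, j) >= 0


@njit(cache=True)
def _ring_insert_after(nbr, deg, i, slot, v):
    """Insert v into i's ring just after position ``slot``."""
    d = deg[i]
    for t in range(d, slot + 1, -1):
        nbr[i, t] = nbr[i, t - 1]
    nbr[i, slot + 1] = v
    deg[i] = d + 1


@njit(cache=True)
def _ring_remove_at(nbr, deg, i, slot):
    d = deg[i]
    for t in range(slot, d - 1):
        nbr[i, t] = nbr[i, t + 1]
    nbr[i, d - 1] = -1
    deg[i] = d - 1


@njit(cache=True)
def _ring_replace(nbr, deg, i, old, new):
    t = _ring_find(nbr, deg, i, old)
    nbr[i, t] = new


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _face_area_vol(pos, a, b, c):
    """Area of triangle (a,b,c) and signed tetra volume against the origin."""
    ax, ay, az = pos[a, 0], pos[a, 1], pos[a, 2]
    bx, by, bz = pos[b, 0], pos[b, 1], pos[b, 2]
    cx, cy, cz = pos[c, 0], pos[c, 1], pos[c, 2]
    # cross(b - a, c - a)
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    area = 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
    # signed volume of tetra (0, a, b, c)
    vol = (ax * (by * cz - bz * cy)
           - ay * (bx * cz - bz * cx)
           + az * (bx * cy - by * cx)) / 6.0
    return area, vol


@njit(cache=True, fastmath=True, inline="always")
def _cot(ox, oy, oz, px, py, pz, qx, qy, qz):
    """Cotangent of the angle at o in triangle (o, p, q)."""
    ux, uy, uz = px - ox, py - oy, pz - oz
    vx, vy, vz = qx - ox, qy - oy, qz - oz
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    cr = np.sqrt(cx * cx + cy * cy + cz * cz)
    if cr < 1.0e-14:
        return 1.0e14
    return dot / cr


@njit(cache=True, fastmath=True)
def _vertex_bend(pos, nbr, deg, v, kappa):
    """Cotangent-Laplacian bending energy attributed to vertex v.

    e_v = (kappa/8) |sum_j (cot a_ij + cot b_ij)(r_v - r_j)|^2 / A_v
    with A_v the barycentric (one-third) vertex area.  This equals
    (kappa/2) (2H_v)^2 A_v for the discrete mean curvature H_v.
    """
    d = deg[v]
    vx, vy, vz = pos[v, 0], pos[v, 1], pos[v, 2]
    sx = 0.0
    sy = 0.0
    sz = 0.0
    av = 0.0
    for t in range(d):
        j = nbr[v, t]
        k = nbr[v, (t + 1) % d]
        jx, jy, jz = pos[j, 0], pos[j, 1], pos[j, 2]
        kx, ky, kz = pos[k, 0], pos[k, 1], pos[k, 2]
        area, _ = _face_area_vol(pos, v, j, k)
        if area < 1.0e-12:
            return BIG_ENERGY
        av += area / 3.0
        # angle at k is opposite edge (v, j); angle at j opposite (v, k)
        ck = _cot(kx, ky, kz, vx, vy, vz, jx, jy, jz)
        cj = _cot(jx, jy, jz, vx, vy, vz, kx, ky, kz)
        sx += ck * (vx - jx) + cj * (vx - kx)
        sy += ck * (vy - jy) + cj * (vy - ky)
        sz += ck * (vz - jz) + cj * (vz - kz)
    return kappa * (sx * sx + sy * sy + sz * sz) / (8.0 * av)


@njit(cache=True, fastmath=True)
def _vertex_faces_av(pos, nbr, deg, v, ka, a0):
    """(area, signed volume, harmonic area energy) summed over faces at v."""
    d = deg[v]
    area_s = 0.0
    vol_s = 0.0
    ea_s = 0.0
    for t in range(d):
        j = nbr[v, t]
        k = nbr[v, (t + 1) % d]
        area, vol = _face_area_vol(pos, v, j, k)
        area_s += area
        vol_s += vol
        da = area - a0
        ea_s += 0.5 * ka * da * da
    return area_s, vol_s, ea_s


@njit(cache=True, fastmath=True)
def _tether_ok_vertex(pos, nbr, deg, v, lmin2, lmax2):
    d = deg[v]
    vx, vy, vz = pos[v, 0], pos[v, 1], pos[v, 2]
    for t in range(d):
        j = nbr[v, t]
        dx = pos[j, 0] - vx
        dy = pos[j, 1] - vy
        dz = pos[j, 2] - vz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < lmin2 or r2 > lmax2:
            return False
    return True


@njit(cache=True, fastmath=True, inline="always")
def _dist2(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return dx * dx + dy * dy + dz * dz


# ---------------------------------------------------------------------------
# global recomputation (from-scratch oracle for the incremental totals)
# ---------------------------------------------------------------------------

@njit(cache=True)
def compute_totals(pos, nbr, deg, vlist, nv, eb, kappa, ka, a0):
    """Recompute all energies/geometry from scratch; refreshes the eb cache.

    Returns (E_bend, E_area, area, volume).  Faces are visited once by
    attributing each to its minimum-id vertex.
    """
    ebend = 0.0
    earea = 0.0
    area_tot = 0.0
    vol_tot = 0.0
    for s in range(nv):
        v = vlist[s]
        e = _vertex_bend(pos, nbr, deg, v, kappa)
        eb[v] = e
        ebend += e
        d = deg[v]
        for t in range(d):
            j = nbr[v, t]
            k = nbr[v, (t + 1) % d]
            if v < j and v < k:
                area, vol = _face_area_vol(pos, v, j, k)
                area_tot += area
                vol_tot += vol
                da = area - a0
                earea += 0.5 * ka * da * da
    return ebend, earea, area_tot, vol_tot


@njit(cache=True)
def check_tether_all(pos, nbr, deg, vlist, nv, lmin2, lmax2):
    for s in range(nv):
        if not _tether_ok_vertex(pos, nbr, deg, vlist[s], lmin2, lmax2):
            return False
    return True


# ---------------------------------------------------------------------------
# bookkeeping helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _d4_add(d4list, d4index, sc_i, v):
    n = sc_i[N4]
    d4list[n] = v
    d4index[v] = n
    sc_i[N4] = n + 1


@njit(cache=True, inline="always")
def _d4_remove(d4list, d4index, sc_i, v):
    n = sc_i[N4] - 1
    t = d4index[v]
    last = d4list[n]
    d4list[t] = last
    d4index[last] = t
    d4index[v] = -1
    sc_i[N4] = n


@njit(cache=True)
def _deg_transition(d4list, d4index, sc_i, v, old, new):
    if old == 4 and new != 4:
        _d4_remove(d4list, d4index, sc_i, v)
    elif new == 4 and old != 4:
        _d4_add(d4list, d4index, sc_i, v)


# ---------------------------------------------------------------------------
# topological surgery (rings only; callers handle snapshots and bookkeeping)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _apply_flip(nbr, deg, i, j, k, l):
    """Replace edge (i,j) (faces (i,j,k),(j,i,l)) by edge (k,l)."""
    _ring_remove_at(nbr, deg, i, _ring_find(nbr, deg, i, j))
    _ring_remove_at(nbr, deg, j, _ring_find(nbr, deg, j, i))
    _ring_insert_after(nbr, deg, k, _ring_find(nbr, deg, k, i), l)
    _ring_insert_after(nbr, deg, l, _ring_find(nbr, deg, l, j), k)


@njit(cache=True)
def _apply_insert(nbr, deg, i, j, k, l, m):
    """Split edge (i,j) with new vertex m; k,l are the face-opposite ids."""
    _ring_replace(nbr, deg, i, j, m)
    _ring_replace(nbr, deg, j, i, m)
    _ring_insert_after(nbr, deg, k, _ring_find(nbr, deg, k, i), m)
    _ring_insert_after(nbr, deg, l, _ring_find(nbr, deg, l, j), m)
    nbr[m, 0] = k
    nbr[m, 1] = i
    nbr[m, 2] = l
    nbr[m, 3] = j
    deg[m] = 4


@njit(cache=True)
def _apply_remove(nbr, deg, m, a, b, c, d):
    """Delete degree-4 vertex m (ring a,b,c,d) and add the diagonal (a,c)."""
    _ring_replace(nbr, deg, a, m, c)
    _ring_replace(nbr, deg, c, m, a)
    _ring_remove_at(nbr, deg, b, _ring_find(nbr, deg, b, m))
    _ring_remove_at(nbr, deg, d, _ring_find(nbr, deg, d, m))
    deg[m] = 0


@njit(cache=True)
def _snapshot_rows(nbr, deg, ids, n, snap_nbr, snap_deg):
    for t in range(n):
        v = ids[t]
        snap_deg[t] = deg[v]
        for s in range(nbr.shape[1]):
            snap_nbr[t, s] = nbr[v, s]


@njit(cache=True)
def _restore_rows(nbr, deg, ids, n, snap_nbr, snap_deg):
    for t in range(n):
        v = ids[t]
        deg[v] = snap_deg[t]
        for s in range(nbr.shape[1]):
            nbr[v, s] = snap_nbr[t, s]


# ---------------------------------------------------------------------------
# move attempts
# ---------------------------------------------------------------------------
# params vector layout (float64):
(P_KAPPA, P_KA, P_A0, P_LMIN2, P_LMAX2, P_MU, P_DP, P_STEP, P_PFLIP,
 P_PEXCH, P_HCUBE) = 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10


@njit(cache=True)
def attempt_translate(pos, nbr, deg, eb, sc_f, p, v, dx, dy, dz):
    d = deg[v]
    # energies before
    eb_before = eb[v]
    for t in range(d):
        eb_before += eb[nbr[v, t]]
    a_b, v_b, ea_b = _vertex_faces_av(pos, nbr, deg, v, p[P_KA], p[P_A0])

    ox, oy, oz = pos[v, 0], pos[v, 1], pos[v, 2]
    pos[v, 0] = ox + dx
    pos[v, 1] = oy + dy
    pos[v, 2] = oz + dz

    if not _tether_ok_vertex(pos, nbr, deg, v, p[P_LMIN2], p[P_LMAX2]):
        pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
        return REJECTED

    new_eb = np.empty(deg[v] + 1)
    new_eb[0] = _vertex_bend(pos, nbr, deg, v, p[P_KAPPA])
    eb_after = new_eb[0]
    ok = new_eb[0] < BIG_ENERGY
    if ok:
        for t in range(d):
            e = _vertex_bend(pos, nbr, deg, nbr[v, t], p[P_KAPPA])
            new_eb[t + 1] = e
            eb_after += e
            if e >= BIG_ENERGY:
                ok = False
                break
    if not ok:
        pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
        return REJECTED

    a_a, v_a, ea_a = _vertex_faces_av(pos, nbr, deg, v, p[P_KA], p[P_A0])
    dphi = (eb_after - eb_before) + (ea_a - ea_b) - p[P_DP] * (v_a - v_b)
    if dphi > 0.0 and np.random.random() >= np.exp(-dphi):
        pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
        return REJECTED

    eb[v] = new_eb[0]
    for t in range(d):
        eb[nbr[v, t]] = new_eb[t + 1]
    sc_f[EBEND] += eb_after - eb_before
    sc_f[EAREA] += ea_a - ea_b
    sc_f[AREA] += a_a - a_b
    sc_f[VOL] += v_a - v_b
    return ACCEPTED


@njit(cache=True)
def flip_partners(nbr, deg, i, j):
    """Face-opposite vertices (k, l) of edge (i, j): faces (i,j,k), (j,i,l)."""
    t = _ring_find(nbr, deg, i, j)
    d = deg[i]
    k = nbr[i, (t + 1) % d]
    l = nbr[i, (t - 1) % d]
    return k, l


@njit(cache=True)
def attempt_flip(pos, nbr, deg, eb, d4list, d4index, sc_i, sc_f, p, i, j,
                 maxdeg):
    k, l = flip_partners(nbr, deg, i, j)
    if deg[i] <= 3 or deg[j] <= 3:
        return INVALID
    if deg[k] >= maxdeg or deg[l] >= maxdeg:
        return INVALID
    if _adjacent(nbr, deg, k, l):
        return INVALID
    d2 = _dist2(pos, k, l)
    if d2 < p[P_LMIN2] or d2 > p[P_LMAX2]:
        return REJECTED

    ids = np.empty(4, dtype=np.int32)
    ids[0], ids[1], ids[2], ids[3] = i, j, k, l
    eb_before = eb[i] + eb[j] + eb[k] + eb[l]
    a1, v1 = _face_area_vol(pos, i, j, k)
    a2, v2 = _face_area_vol(pos, j, i, l)
    da1 = a1 - p[P_A0]
    da2 = a2 - p[P_A0]
    ea_b = 0.5 * p[P_KA] * (da1 * da1 + da2 * da2)

    snap_nbr = np.empty((4, nbr.shape[1]), dtype=np.int32)
    snap_deg = np.empty(4, dtype=np.int32)
    _snapshot_rows(nbr, deg, ids, 4, snap_nbr, snap_deg)
    _apply_flip(nbr, deg, i, j, k, l)

    new_eb = np.empty(4)
    eb_after = 0.0
    ok = True
    for t in range(4):
        e = _vertex_bend(pos, nbr, deg, ids[t], p[P_KAPPA])
        new_eb[t] = e
        eb_after += e
        if e >= BIG_ENERGY:
            ok = False
            break
    a3, v3 = _face_area_vol(pos, k, i, l)
    a4, v4 = _face_area_vol(pos, l, j, k)
    da3 = a3 - p[P_A0]
    da4 = a4 - p[P_A0]
    ea_a = 0.5 * p[P_KA] * (da3 * da3 + da4 * da4)

    if ok:
        dphi = (eb_after - eb_before) + (ea_a - ea_b) \
            - p[P_DP] * ((v3 + v4) - (v1 + v2))
        if dphi > 0.0 and np.random.random() >= np.exp(-dphi):
            ok = False

    if not ok:
        _restore_rows(nbr, deg, ids, 4, snap_nbr, snap_deg)
        return REJECTED

    for t in range(4):
        eb[ids[t]] = new_eb[t]
    sc_f[EBEND] += eb_after - eb_before
    sc_f[EAREA] += ea_a - ea_b
    sc_f[AREA] += (a3 + a4) - (a1 + a2)
    sc_f[VOL] += (v3 + v4) - (v1 + v2)
    _deg_transition(d4list, d4index, sc_i, i, snap_deg[0], deg[i])
    _deg_transition(d4list, d4index, sc_i, j, snap_deg[1], deg[j])
    _deg_transition(d4list, d4index, sc_i, k, snap_deg[2], deg[k])
    _deg_transition(d4list, d4index, sc_i, l, snap_deg[3], deg[l])
    return ACCEPTED


@njit(cache=True)
def insert_gen_ratio(deg, sc_i, k, l, h3):
    """Pgen(reverse removal) / Pgen(forward insertion) for an edge split.

    Forward: the edge is drawn uniformly among E = 3*nv - 6 edges and the
    new vertex position uniformly in a cube of volume h3 around the edge
    midpoint (proposal density 1/(E*h3)).  Reverse: the inverse removal
    draws uniformly among the 2*n4' ordered (degree-4 vertex, diagonal)
    pairs of the post-insertion mesh.  The position-space window makes the
    insertion/removal pair measure-consistent, which a deterministic
    midpoint placement (a delta-function proposal density) would not be.
    """
    nv = sc_i[NV]
    ne = 3 * nv - 6
    n4_post = sc_i[N4] + 1
    if deg[k] == 3:
        n4_post += 1
    elif deg[k] == 4:
        n4_post -= 1
    if deg[l] == 3:
        n4_post += 1
    elif deg[l] == 4:
        n4_post -= 1
    return ne * h3 / (2.0 * n4_post)


@njit(cache=True)
def attempt_insert(pos, nbr, deg, eb, vlist, vindex, d4list, d4index,
                   freelist, sc_i, sc_f, p, i, j, maxdeg):
    k, l = flip_partners(nbr, deg, i, j)
    if deg[k] >= maxdeg or deg[l] >= maxdeg:
        return INVALID
    if sc_i[NFREE] <= 0:
        return INVALID
    m = freelist[sc_i[NFREE] - 1]

    h = p[P_HCUBE]
    pos[m, 0] = 0.5 * (pos[i, 0] + pos[j, 0]) + h * (np.random.random() - 0.5)
    pos[m, 1] = 0.5 * (pos[i, 1] + pos[j, 1]) + h * (np.random.random() - 0.5)
    pos[m, 2] = 0.5 * (pos[i, 2] + pos[j, 2]) + h * (np.random.random() - 0.5)
    # tether screen on the four edges created at m
    quad = np.empty(4, dtype=np.int32)
    quad[0], quad[1], quad[2], quad[3] = i, j, k, l
    for t in range(4):
        d2 = _dist2(pos, m, quad[t])
        if d2 < p[P_LMIN2] or d2 > p[P_LMAX2]:
            return REJECTED

    gen_ratio = insert_gen_ratio(deg, sc_i, k, l, h * h * h)

    ids = np.empty(5, dtype=np.int32)
    ids[0], ids[1], ids[2], ids[3], ids[4] = i, j, k, l, m
    eb_before = eb[i] + eb[j] + eb[k] + eb[l]
    a1, v1 = _face_area_vol(pos, i, j, k)
    a2, v2 = _face_area_vol(pos, j, i, l)
    da1 = a1 - p[P_A0]
    da2 = a2 - p[P_A0]
    ea_b = 0.5 * p[P_KA] * (da1 * da1 + da2 * da2)

    snap_nbr = np.empty((5, nbr.shape[1]), dtype=np.int32)
    snap_deg = np.empty(5, dtype=np.int32)
    _snapshot_rows(nbr, deg, ids, 5, snap_nbr, snap_deg)
    _apply_insert(nbr, deg, i, j, k, l, m)

    new_eb = np.empty(5)
    eb_after = 0.0
    ok = True
    for t in range(5):
        e = _vertex_bend(pos, nbr, deg, ids[t], p[P_KAPPA])
        new_eb[t] = e
        eb_after += e
        if e >= BIG_ENERGY:
            ok = False
            break
    ea_a = 0.0
    a_a = 0.0
    v_a = 0.0
    # new faces: (i,m,k), (m,j,k), (j,m,l), (m,i,l)
    f_a = np.empty((4, 3), dtype=np.int32)
    f_a[0, 0], f_a[0, 1], f_a[0, 2] = i, m, k
    f_a[1, 0], f_a[1, 1], f_a[1, 2] = m, j, k
    f_a[2, 0], f_a[2, 1], f_a[2, 2] = j, m, l
    f_a[3, 0], f_a[3, 1], f_a[3, 2] = m, i, l
    for t in range(4):
        ar, vo = _face_area_vol(pos, f_a[t, 0], f_a[t, 1], f_a[t, 2])
        a_a += ar
        v_a += vo
        da = ar - p[P_A0]
        ea_a += 0.5 * p[P_KA] * da * da

    if ok:
        dphi = (eb_after - eb_before) + (ea_a - ea_b) - p[P_MU] \
            - p[P_DP] * (v_a - (v1 + v2))
        x = gen_ratio * np.exp(-min(dphi, 500.0))
        if x < 1.0 and np.random.random() >= x:
            ok = False

    if not ok:
        _restore_rows(nbr, deg, ids, 5, snap_nbr, snap_deg)
        return REJECTED

    for t in range(5):
        eb[ids[t]] = new_eb[t]
    sc_f[EBEND] += eb_after - eb_before
    sc_f[EAREA] += ea_a - ea_b
    sc_f[AREA] += a_a - (a1 + a2)
    sc_f[VOL] += v_a - (v1 + v2)
    # bookkeeping: m becomes alive with degree 4; k and l gained an edge
    sc_i[NFREE] -= 1
    nv = sc_i[NV]
    vlist[nv] = m
    vindex[m] = nv
    sc_i[NV] = nv + 1
    _d4_add(d4list, d4index, sc_i, m)
    _deg_transition(d4list, d4index, sc_i, k, snap_deg[2], deg[k])
    _deg_transition(d4list, d4index, sc_i, l, snap_deg[3], deg[l])
    return ACCEPTED


@njit(cache=True)
def removal_quad(nbr, deg, m, diag):
    """Ring (a, b, c, d) of the degree-4 vertex m, rotated so the proposed
    diagonal is (a, c).  diag selects which of the two diagonals."""
    if diag == 0:
        return nbr[m, 0], nbr[m, 1], nbr[m, 2], nbr[m, 3]
    return nbr[m, 1], nbr[m, 2], nbr[m, 3], nbr[m, 0]


@njit(cache=True)
def attempt_remove(pos, nbr, deg, eb, vlist, vindex, d4list, d4index,
                   freelist, sc_i, sc_f, p, m, diag):
    if deg[m] != 4 or sc_i[NV] <= sc_i[NMIN]:
        return INVALID
    a, b, c, d = removal_quad(nbr, deg, m, diag)
    if deg[b] <= 3 or deg[d] <= 3:
        return INVALID
    if _adjacent(nbr, deg, a, c):
        return INVALID
    d2 = _dist2(pos, a, c)
    if d2 < p[P_LMIN2] or d2 > p[P_LMAX2]:
        return REJECTED
    # the reverse insertion can only generate positions inside the cube of
    # side h around the diagonal midpoint; outside it Pgen(reverse) = 0
    h = p[P_HCUBE]
    half = 0.5 * h
    if (abs(pos[m, 0] - 0.5 * (pos[a, 0] + pos[c, 0])) > half
            or abs(pos[m, 1] - 0.5 * (pos[a, 1] + pos[c, 1])) > half
            or abs(pos[m, 2] - 0.5 * (pos[a, 2] + pos[c, 2])) > half):
        return REJECTED

    # reverse move: edge split of diagonal (a,c) on the post-removal mesh
    ne_post = 3 * (sc_i[NV] - 1) - 6
    gen_ratio = (2.0 * sc_i[N4]) / (ne_post * h * h * h)

    ids = np.empty(5, dtype=np.int32)
    ids[0], ids[1], ids[2], ids[3], ids[4] = m, a, b, c, d
    eb_before = eb[m] + eb[a] + eb[b] + eb[c] + eb[d]
    ea_b = 0.0
    a_b = 0.0
    v_b = 0.0
    f_b = np.empty((4, 3), dtype=np.int32)
    f_b[0, 0], f_b[0, 1], f_b[0, 2] = m, a, b
    f_b[1, 0], f_b[1, 1], f_b[1, 2] = m, b, c
    f_b[2, 0], f_b[2, 1], f_b[2, 2] = m, c, d
    f_b[3, 0], f_b[3, 1], f_b[3, 2] = m, d, a
    for t in range(4):
        ar, vo = _face_area_vol(pos, f_b[t, 0], f_b[t, 1], f_b[t, 2])
        a_b += ar
        v_b += vo
        dar = ar - p[P_A0]
        ea_b += 0.5 * p[P_KA] * dar * dar

    snap_nbr = np.empty((5, nbr.shape[1]), dtype=np.int32)
    snap_deg = np.empty(5, dtype=np.int32)
    _snapshot_rows(nbr, deg, ids, 5, snap_nbr, snap_deg)
    _apply_remove(nbr, deg, m, a, b, c, d)

    new_eb = np.empty(4)
    eb_after = 0.0
    ok = True
    for t in range(4):
        e = _vertex_bend(pos, nbr, deg, ids[t + 1], p[P_KAPPA])
        new_eb[t] = e
        eb_after += e
        if e >= BIG_ENERGY:
            ok = False
            break
    a1, v1 = _face_area_vol(pos, a, b, c)
    a2, v2 = _face_area_vol(pos, a, c, d)
    da1 = a1 - p[P_A0]
    da2 = a2 - p[P_A0]
    ea_a = 0.5 * p[P_KA] * (da1 * da1 + da2 * da2)

    if ok:
        dphi = (eb_after - eb_before) + (ea_a - ea_b) + p[P_MU] \
            - p[P_DP] * ((v1 + v2) - v_b)
        x = gen_ratio * np.exp(-min(dphi, 500.0))
        if x < 1.0 and np.random.random() >= x:
            ok = False

    if not ok:
        _restore_rows(nbr, deg, ids, 5, snap_nbr, snap_deg)
        return REJECTED

    for t in range(4):
        eb[ids[t + 1]] = new_eb[t]
    eb[m] = 0.0
    sc_f[EBEND] += eb_after - eb_before
    sc_f[EAREA] += ea_a - ea_b
    sc_f[AREA] += (a1 + a2) - a_b
    sc_f[VOL] += (v1 + v2) - v_b
    # bookkeeping: m dies; b and d lost an edge
    _d4_remove(d4list, d4index, sc_i, m)
    nv = sc_i[NV] - 1
    t_m = vindex[m]
    last = vlist[nv]
    vlist[t_m] = last
    vindex[last] = t_m
    vindex[m] = -1
    sc_i[NV] = nv
    freelist[sc_i[NFREE]] = m
    sc_i[NFREE] += 1
    _deg_transition(d4list, d4index, sc_i, b, snap_deg[2], deg[b])
    _deg_transition(d4list, d4index, sc_i, d, snap_deg[4], deg[d])
    return ACCEPTED


# ---------------------------------------------------------------------------
# sweep scheduling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pick_edge(nbr, deg, vlist, nv, maxdeg):
    """Uniformly random directed edge via degree-weighted rejection."""
    while True:
        i = vlist[np.random.randint(nv)]
        if np.random.randint(maxdeg) < deg[i]:
            j = nbr[i, np.random.randint(deg[i])]
            return i, j


@njit(cache=True)
def run_sweeps(pos, nbr, deg, eb, vlist, vindex, d4list, d4index, freelist,
               sc_i, sc_f, p, nsweeps, maxdeg, seed, acc, up_counts,
               down_counts, n_trace):
    """Run ``nsweeps`` Monte Carlo sweeps.

    Per sweep: exactly N vertex translations, Binomial(E, pflip) edge
    flips and Binomial(E, pexchange) insertion and removal attempts each,
    interleaved in uniformly random order.  ``acc`` accumulates
    (attempted, accepted) per move kind (shape (4, 2)).  Accepted
    insertions at vertex count n increment ``up_counts[n]``; accepted
    removals at n increment ``down_counts[n]`` (for detailed-balance
    audits).  ``n_trace[s]`` records the vertex count after sweep s.
    """
    if seed >= 0:
        np.random.seed(seed)
    step = p[P_STEP]
    for sw in range(nsweeps):
        nv0 = sc_i[NV]
        ne = 3 * nv0 - 6
        cnt = np.empty(4, dtype=np.int64)
        cnt[TRANSLATE] = nv0
        cnt[FLIP] = np.random.binomial(ne, min(p[P_PFLIP], 1.0))
        cnt[INSERT] = np.random.binomial(ne, min(p[P_PEXCH], 1.0))
        cnt[REMOVE] = np.random.binomial(ne, min(p[P_PEXCH], 1.0))
        remaining = cnt[0] + cnt[1] + cnt[2] + cnt[3]
        while remaining > 0:
            r = np.random.randint(remaining)
            kind = 0
            acc_c = cnt[0]
            while r >= acc_c:
                kind += 1
                acc_c += cnt[kind]
            cnt[kind] -= 1
            remaining -= 1
            acc[kind, 0] += 1
            if kind == TRANSLATE:
                v = vlist[np.random.randint(sc_i[NV])]
                dx = step * (2.0 * np.random.random() - 1.0)
                dy = step * (2.0 * np.random.random() - 1.0)
                dz = step * (2.0 * np.random.random() - 1.0)
                if attempt_translate(pos, nbr, deg, eb, sc_f, p, v,
                                     dx, dy, dz) == ACCEPTED:
                    acc[kind, 1] += 1
            elif kind == FLIP:
                i, j = _pick_edge(nbr, deg, vlist, sc_i[NV], maxdeg)
                if attempt_flip(pos, nbr, deg, eb, d4list, d4index, sc_i,
                                sc_f, p, i, j, maxdeg) == ACCEPTED:
                    acc[kind, 1] += 1
            elif kind == INSERT:
                i, j = _pick_edge(nbr, deg, vlist, sc_i[NV], maxdeg)
                n_now = sc_i[NV]
                if attempt_insert(pos, nbr, deg, eb, vlist, vindex, d4list,
                                  d4index, freelist, sc_i, sc_f, p, i, j,
                                  maxdeg) == ACCEPTED:
                    acc[kind, 1] += 1
                    if n_now < up_counts.shape[0]:
                        up_counts[n_now] += 1
            else:
                n4 = sc_i[N4]
                if n4 > 0:
                    r2 = np.random.randint(2 * n4)
                    m = d4list[r2 >> 1]
                    n_now = sc_i[NV]
                    if attempt_remove(pos, nbr, deg, eb, vlist, vindex,
                                      d4list, d4index, freelist, sc_i, sc_f,
                                      p, m, r2 & 1) == ACCEPTED:
                        acc[kind, 1] += 1
                        if n_now < down_counts.shape[0]:
                            down_counts[n_now] += 1
        if n_trace.shape[0] > sw:
            n_trace[sw] = sc_i[NV]
    return 0
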