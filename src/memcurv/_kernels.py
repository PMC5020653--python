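"""Numba kernels for the vesicle Monte Carlo engine.

Everything here operates on flat arrays (struct-of-arrays layout) so that a
full sweep over thousands of vertices runs in compiled code.  Incremental
energy bookkeeping is used throughout: a vertex move touches only its
incident faces and their edges, an edge flip only the two faces of the quad.
The Python layer (:mod:`memcurv.montecarlo`) verifies the running totals
against a from-scratch recompute, which pins down the bookkeeping.

Parameter vector layout (``par``, float64):

== ==========================================
0  l_min^2
1  l_max^2
2  kappa_disc (prefactor of (1/2)|n_i-n_j|^2)
3  K_A                 [kBT / l^2]
4  K_V                 [kBT / l^3]
5  A_t
6  V_t
7  epsilon
8  cos(theta_wr)
9  l_m
10 r_cut
11 (l_m/r_cut)^6        (well shift)
12 well kind: 0 = power6, 1 = square
13 D_p^2  (particle-particle hard core, squared)
14 vertex move amplitude (half-side of displacement cube)
15 particle move amplitude
16 box half-size L (moves leaving the box are rejected)
== ==========================================

Running totals (``acc``, float64): [area, volume, E_bend, E_adh].
Counter layout (``counters`` int64, shape (4, 2)): rows
vertex/flip/particle/aspect, columns attempts/accepts.
"""

import numpy as np
from numba import njit

MAXDEG = 16

V_MOVE, F_MOVE, P_MOVE, A_MOVE = 0, 1, 2, 3
_INF = 1.0e300


@njit(cache=True)
def accept_trials(dE, T, n, seed):
    """Count Metropolis acceptances for a fixed energy difference.

    Uses the same acceptance rule as every move kernel; exposed so the rule
    itself can be checked against the closed form min(1, exp(-dE/T)).
    """
    np.random.seed(seed)
    acc = 0
    for _ in range(n):
        if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
            acc += 1
    return acc


@njit(cache=True)
def two_state_occupancy(dE, T, n, seed):
    """Occupancy of the excited state of a two-level system under Metropolis.

    A chain on states {0, 1} with energies {0, dE}; each step proposes the
    other state and applies the Metropolis rule.  Returns time spent in
    state 1, which must approach n * p with p = exp(-dE/T)/(1+exp(-dE/T)).
    """
    np.random.seed(seed)
    state = 0
    count = 0
    for _ in range(n):
        d = dE if state == 0 else -dE
        if d <= 0.0 or np.random.random() < np.exp(-d / T):
            state = 1 - state
        count += state
    return count


@njit(cache=True)
def _face_geom(pos, a, b, c):
    """Unit normal, area and 6x signed volume contribution of face (a,b,c)."""
    ax, ay, az = pos[a, 0], pos[a, 1], pos[a, 2]
    ux, uy, uz = pos[b, 0] - ax, pos[b, 1] - ay, pos[b, 2] - az
    vx, vy, vz = pos[c, 0] - ax, pos[c, 1] - ay, pos[c, 2] - az
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    vol6 = (ax * (pos[b, 1] * pos[c, 2] - pos[b, 2] * pos[c, 1])
            + ay * (pos[b, 2] * pos[c, 0] - pos[b, 0] * pos[c, 2])
            + az * (pos[b, 0] * pos[c, 1] - pos[b, 1] * pos[c, 0]))
    if nn < 1e-300:
        return 0.0, 0.0, 0.0, 0.0, vol6
    return nx / nn, ny / nn, nz / nn, 0.5 * nn, vol6


@njit(cache=True)
def _face_geom_moved(pos, a, b, c, v, px, py, pz):
    """Same as _face_geom but with vertex ``v`` virtually at (px,py,pz)."""
    if a == v:
        axx, ayy, azz = px, py, pz
    else:
        axx, ayy, azz = pos[a, 0], pos[a, 1], pos[a, 2]
    if b == v:
        bxx, byy, bzz = px, py, pz
    else:
        bxx, byy, bzz = pos[b, 0], pos[b, 1], pos[b, 2]
    if c == v:
        cxx, cyy, czz = px, py, pz
    else:
        cxx, cyy, czz = pos[c, 0], pos[c, 1], pos[c, 2]
    ux, uy, uz = bxx - axx, byy - ayy, bzz - azz
    vx, vy, vz = cxx - axx, cyy - ayy, czz - azz
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    vol6 = (axx * (byy * czz - bzz * cyy)
            + ayy * (bzz * cxx - bxx * czz)
            + azz * (bxx * cyy - byy * cxx))
    if nn < 1e-300:
        return 0.0, 0.0, 0.0, 0.0, vol6
    return nx / nn, ny / nn, nz / nn, 0.5 * nn, vol6


@njit(cache=True)
def _adh_one(px, py, pz, ppos, paxis, p, par):
    """Adhesion energy of one vertex position against particle ``p``.

    Returns +inf when the vertex violates the particle hard core.
    """
    dx = px - ppos[p, 0]
    dy = py - ppos[p, 1]
    dz = pz - ppos[p, 2]
    r2 = dx * dx + dy * dy + dz * dz
    l_m = par[9]
    if r2 < l_m * l_m * (1.0 - 1e-12):
        return _INF
    r = np.sqrt(r2)
    if r > par[10]:
        return 0.0
    ct = (dx * paxis[p, 0] + dy * paxis[p, 1] + dz * paxis[p, 2]) / r
    if ct < par[8]:
        return 0.0
    if par[12] == 1.0:
        w = 1.0
    else:
        shift = par[11]
        w = ((l_m / r) ** 6 - shift) / (1.0 - shift)
    return -par[7] * w


@njit(cache=True)
def _constraint_u(area, vol, par):
    ua = par[3] * (area - par[5]) * (area - par[5]) / par[5]
    uv = par[4] * (vol - par[6]) * (vol - par[6]) / par[6]
    return ua + uv


# ---------------------------------------------------------------------------
# cell list (hard-core neighbour queries); cell size is 1 l = l_min
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cell_index(x, y, z, L, ncx):
    ix = int(np.floor(x + L))
    iy = int(np.floor(y + L))
    iz = int(np.floor(z + L))
    return ix + ncx * (iy + ncx * iz)


@njit(cache=True)
def build_cells(pos, L, ncx, head, nxt, vcell):
    head[:] = -1
    n = pos.shape[0]
    for v in range(n):
        ci = _cell_index(pos[v, 0], pos[v, 1], pos[v, 2], L, ncx)
        vcell[v] = ci
        nxt[v] = head[ci]
        head[ci] = v


@njit(cache=True)
def _hardcore_clash(pos, v, px, py, pz, lmin2, L, ncx, head, nxt):
    """True if moving v to (px,py,pz) violates the vertex hard core.

    A proposal is a clash when another vertex ends up within l_min, unless
    that pair is *already* violating and the move increases its distance
    (repair moves must stay possible so that transient violations, e.g.
    after an externally imposed particle displacement, can heal; for valid
    states the rule is the plain hard core).
    """
    ix = int(np.floor(px + L))
    iy = int(np.floor(py + L))
    iz = int(np.floor(pz + L))
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                jx, jy, jz = ix + dx, iy + dy, iz + dz
                if jx < 0 or jy < 0 or jz < 0 or jx >= ncx or jy >= ncx or jz >= ncx:
                    continue
                u = head[jx + ncx * (jy + ncx * jz)]
                while u != -1:
                    if u != v:
                        ddx = pos[u, 0] - px
                        ddy = pos[u, 1] - py
                        ddz = pos[u, 2] - pz
                        d2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2 < lmin2:
                            ox = pos[u, 0] - pos[v, 0]
                            oy = pos[u, 1] - pos[v, 1]
                            oz = pos[u, 2] - pos[v, 2]
                            cur2 = ox * ox + oy * oy + oz * oz
                            if not (cur2 < lmin2 and d2 > cur2):
                                return True
                    u = nxt[u]
    return False


@njit(cache=True)
def _cell_move(v, px, py, pz, L, ncx, head, nxt, vcell):
    new = _cell_index(px, py, pz, L, ncx)
    old = vcell[v]
    if new == old:
        return
    u = head[old]
    if u == v:
        head[old] = nxt[v]
    else:
        while nxt[u] != v:
            u = nxt[u]
        nxt[u] = nxt[v]
    nxt[v] = head[new]
    head[new] = v
    vcell[v] = new


# ---------------------------------------------------------------------------
# full rebuild of geometry caches and running totals
# ---------------------------------------------------------------------------

@njit(cache=True)
def rebuild(pos, faces, edge_f, fnormal, farea, fvol6, bend_e, adh,
            ppos, paxis, adh_mask, par, acc):
    F = faces.shape[0]
    area = 0.0
    vol6 = 0.0
    for f in range(F):
        nx, ny, nz, a, v6 = _face_geom(pos, faces[f, 0], faces[f, 1], faces[f, 2])
        fnormal[f, 0], fnormal[f, 1], fnormal[f, 2] = nx, ny, nz
        farea[f] = a
        fvol6[f] = v6
        area += a
        vol6 += v6
    eb = 0.0
    for e in range(edge_f.shape[0]):
        f1, f2 = edge_f[e, 0], edge_f[e, 1]
        dot = (fnormal[f1, 0] * fnormal[f2, 0] + fnormal[f1, 1] * fnormal[f2, 1]
               + fnormal[f1, 2] * fnormal[f2, 2])
        bend_e[e] = par[2] * (1.0 - dot)
        eb += bend_e[e]
    ea = 0.0
    P = ppos.shape[0]
    for v in range(pos.shape[0]):
        for p in range(P):
            val = _adh_one(pos[v, 0], pos[v, 1], pos[v, 2], ppos, paxis, p, par)
            if val < _INF and adh_mask[v, p] == 0:
                val = 0.0
            adh[v, p] = val
            ea += val
    acc[0] = area
    acc[1] = vol6 / 6.0
    acc[2] = eb
    acc[3] = ea


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

@njit(cache=True)
def _try_vertex_move(v, px, py, pz, T, pos, faces, face_edges, edge_f,
                     vfaces, vnf, fnormal, farea, fvol6, bend_e, adh,
                     ppos, paxis, adh_mask, par, acc, L, ncx, head, nxt, vcell,
                     tmpn, tmpa, tmpv, tmpf, eids, eterms, adh_new):
    if abs(px) > L - 2.0 or abs(py) > L - 2.0 or abs(pz) > L - 2.0:
        return False
    if _hardcore_clash(pos, v, px, py, pz, par[0], L, ncx, head, nxt):
        return False
    nf = vnf[v]
    # tether upper bound on all incident edges (repair moves on already
    # over-stretched edges stay allowed, cf. _hardcore_clash)
    lmax2 = par[1]
    for i in range(nf):
        f = vfaces[v, i]
        for k in range(3):
            u = faces[f, k]
            if u == v:
                continue
            dx = pos[u, 0] - px
            dy = pos[u, 1] - py
            dz = pos[u, 2] - pz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > lmax2:
                ox = pos[u, 0] - pos[v, 0]
                oy = pos[u, 1] - pos[v, 1]
                oz = pos[u, 2] - pos[v, 2]
                cur2 = ox * ox + oy * oy + oz * oz
                if not (cur2 > lmax2 and d2 < cur2):
                    return False
    # adhesion delta (also enforces particle-vertex hard core)
    P = ppos.shape[0]
    d_adh = 0.0
    for p in range(P):
        val = _adh_one(px, py, pz, ppos, paxis, p, par)
        if val >= _INF:
            return False
        if adh_mask[v, p] == 0:
            val = 0.0
        adh_new[p] = val
        d_adh += val - adh[v, p]
    # geometry of incident faces
    d_area = 0.0
    d_vol6 = 0.0
    for i in range(nf):
        f = vfaces[v, i]
        tmpf[i] = f
        nx, ny, nz, a, v6 = _face_geom_moved(pos, faces[f, 0], faces[f, 1], faces[f, 2],
                                             v, px, py, pz)
        tmpn[i, 0], tmpn[i, 1], tmpn[i, 2] = nx, ny, nz
        tmpa[i] = a
        tmpv[i] = v6
        d_area += a - farea[f]
        d_vol6 += v6 - fvol6[f]
    # affected edges: all edges of the incident faces (deduplicated)
    ne = 0
    for i in range(nf):
        f = vfaces[v, i]
        for k in range(3):
            e = face_edges[f, k]
            seen = False
            for q in range(ne):
                if eids[q] == e:
                    seen = True
                    break
            if not seen:
                eids[ne] = e
                ne += 1
    d_bend = 0.0
    for q in range(ne):
        e = eids[q]
        f1, f2 = edge_f[e, 0], edge_f[e, 1]
        i1 = -1
        i2 = -1
        for i in range(nf):
            if tmpf[i] == f1:
                i1 = i
            if tmpf[i] == f2:
                i2 = i
        if i1 >= 0:
            n1x, n1y, n1z = tmpn[i1, 0], tmpn[i1, 1], tmpn[i1, 2]
        else:
            n1x, n1y, n1z = fnormal[f1, 0], fnormal[f1, 1], fnormal[f1, 2]
        if i2 >= 0:
            n2x, n2y, n2z = tmpn[i2, 0], tmpn[i2, 1], tmpn[i2, 2]
        else:
            n2x, n2y, n2z = fnormal[f2, 0], fnormal[f2, 1], fnormal[f2, 2]
        term = par[2] * (1.0 - (n1x * n2x + n1y * n2y + n1z * n2z))
        eterms[q] = term
        d_bend += term - bend_e[e]
    area_new = acc[0] + d_area
    vol_new = acc[1] + d_vol6 / 6.0
    d_con = _constraint_u(area_new, vol_new, par) - _constraint_u(acc[0], acc[1], par)
    dE = d_bend + d_con + d_adh
    if dE > 0.0:
        if np.random.random() >= np.exp(-dE / T):
            return False
    # commit
    pos[v, 0], pos[v, 1], pos[v, 2] = px, py, pz
    for i in range(nf):
        f = tmpf[i]
        fnormal[f, 0], fnormal[f, 1], fnormal[f, 2] = tmpn[i, 0], tmpn[i, 1], tmpn[i, 2]
        farea[f] = tmpa[i]
        fvol6[f] = tmpv[i]
    for q in range(ne):
        acc[2] += eterms[q] - bend_e[eids[q]]
        bend_e[eids[q]] = eterms[q]
    for p in range(P):
        acc[3] += adh_new[p] - adh[v, p]
        adh[v, p] = adh_new[p]
    acc[0] = area_new
    acc[1] = vol_new
    _cell_move(v, px, py, pz, L, ncx, head, nxt, vcell)
    return True


@njit(cache=True)
def _other_vertex(faces, f, a, b):
    for k in range(3):
        u = faces[f, k]
        if u != a and u != b:
            return u
    return -1


@njit(cache=True)
def _try_flip(e, T, pos, faces, face_edges, edge_v, edge_f, vfaces, vnf,
              fnormal, farea, fvol6, bend_e, par, acc):
    f1, f2 = edge_f[e, 0], edge_f[e, 1]
    lo, hi = edge_v[e, 0], edge_v[e, 1]
    # orient (a, b) so that f1 traverses a -> b
    a = lo
    b = hi
    for k in range(3):
        if faces[f1, k] == lo:
            if faces[f1, (k + 1) % 3] == hi:
                a, b = lo, hi
            else:
                a, b = hi, lo
            break
    c = _other_vertex(faces, f1, a, b)
    d = _other_vertex(faces, f2, a, b)
    # degree bounds: a, b lose a face, c, d gain one
    if vnf[a] <= 3 or vnf[b] <= 3 or vnf[c] >= MAXDEG or vnf[d] >= MAXDEG:
        return False
    # c and d must not already be connected (no face contains both)
    for i in range(vnf[c]):
        f = vfaces[c, i]
        for k in range(3):
            if faces[f, k] == d:
                return False
    # tether bounds on the new edge
    dx = pos[c, 0] - pos[d, 0]
    dy = pos[c, 1] - pos[d, 1]
    dz = pos[c, 2] - pos[d, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < par[0] or r2 > par[1]:
        return False
    # boundary edges of the quad
    e_ac = -1
    e_bc = -1
    for k in range(3):
        ek = face_edges[f1, k]
        if ek == e:
            continue
        u0, u1 = edge_v[ek, 0], edge_v[ek, 1]
        if (u0 == a and u1 == c) or (u0 == c and u1 == a):
            e_ac = ek
        else:
            e_bc = ek
    e_ad = -1
    e_bd = -1
    for k in range(3):
        ek = face_edges[f2, k]
        if ek == e:
            continue
        u0, u1 = edge_v[ek, 0], edge_v[ek, 1]
        if (u0 == a and u1 == d) or (u0 == d and u1 == a):
            e_ad = ek
        else:
            e_bd = ek
    # new face geometry: f1' = (a, d, c), f2' = (b, c, d)
    n1x, n1y, n1z, a1, v1 = _face_geom(pos, a, d, c)
    n2x, n2y, n2z, a2, v2 = _face_geom(pos, b, c, d)
    d_area = a1 + a2 - farea[f1] - farea[f2]
    d_vol6 = v1 + v2 - fvol6[f1] - fvol6[f2]
    # bending terms of the 5 affected edges
    t_e = par[2] * (1.0 - (n1x * n2x + n1y * n2y + n1z * n2z))
    g = edge_f[e_ac, 0] if edge_f[e_ac, 1] == f1 else edge_f[e_ac, 1]
    t_ac = par[2] * (1.0 - (n1x * fnormal[g, 0] + n1y * fnormal[g, 1] + n1z * fnormal[g, 2]))
    g = edge_f[e_ad, 0] if edge_f[e_ad, 1] == f2 else edge_f[e_ad, 1]
    t_ad = par[2] * (1.0 - (n1x * fnormal[g, 0] + n1y * fnormal[g, 1] + n1z * fnormal[g, 2]))
    g = edge_f[e_bc, 0] if edge_f[e_bc, 1] == f1 else edge_f[e_bc, 1]
    t_bc = par[2] * (1.0 - (n2x * fnormal[g, 0] + n2y * fnormal[g, 1] + n2z * fnormal[g, 2]))
    g = edge_f[e_bd, 0] if edge_f[e_bd, 1] == f2 else edge_f[e_bd, 1]
    t_bd = par[2] * (1.0 - (n2x * fnormal[g, 0] + n2y * fnormal[g, 1] + n2z * fnormal[g, 2]))
    d_bend = (t_e + t_ac + t_ad + t_bc + t_bd
              - bend_e[e] - bend_e[e_ac] - bend_e[e_ad] - bend_e[e_bc] - bend_e[e_bd])
    area_new = acc[0] + d_area
    vol_new = acc[1] + d_vol6 / 6.0
    d_con = _constraint_u(area_new, vol_new, par) - _constraint_u(acc[0], acc[1], par)
    dE = d_bend + d_con
    if dE > 0.0:
        if np.random.random() >= np.exp(-dE / T):
            return False
    # commit: rewrite faces, edges, incidence
    faces[f1, 0], faces[f1, 1], faces[f1, 2] = a, d, c
    faces[f2, 0], faces[f2, 1], faces[f2, 2] = b, c, d
    face_edges[f1, 0], face_edges[f1, 1], face_edges[f1, 2] = e, e_ad, e_ac
    face_edges[f2, 0], face_edges[f2, 1], face_edges[f2, 2] = e, e_bc, e_bd
    if c < d:
        edge_v[e, 0], edge_v[e, 1] = c, d
    else:
        edge_v[e, 0], edge_v[e, 1] = d, c
    # e_bc moves from f1 to f2; e_ad moves from f2 to f1
    if edge_f[e_bc, 0] == f1:
        edge_f[e_bc, 0] = f2
    else:
        edge_f[e_bc, 1] = f2
    if edge_f[e_ad, 0] == f2:
        edge_f[e_ad, 0] = f1
    else:
        edge_f[e_ad, 1] = f1
    # vertex-face incidence: a loses f2, b loses f1, c gains f2, d gains f1
    for i in range(vnf[a]):
        if vfaces[a, i] == f2:
            vfaces[a, i] = vfaces[a, vnf[a] - 1]
            vnf[a] -= 1
            break
    for i in range(vnf[b]):
        if vfaces[b, i] == f1:
            vfaces[b, i] = vfaces[b, vnf[b] - 1]
            vnf[b] -= 1
            break
    vfaces[c, vnf[c]] = f2
    vnf[c] += 1
    vfaces[d, vnf[d]] = f1
    vnf[d] += 1
    fnormal[f1, 0], fnormal[f1, 1], fnormal[f1, 2] = n1x, n1y, n1z
    fnormal[f2, 0], fnormal[f2, 1], fnormal[f2, 2] = n2x, n2y, n2z
    farea[f1] = a1
    farea[f2] = a2
    fvol6[f1] = v1
    fvol6[f2] = v2
    acc[2] += t_e - bend_e[e] + t_ac - bend_e[e_ac] + t_ad - bend_e[e_ad] \
        + t_bc - bend_e[e_bc] + t_bd - bend_e[e_bd]
    bend_e[e] = t_e
    bend_e[e_ac] = t_ac
    bend_e[e_ad] = t_ad
    bend_e[e_bc] = t_bc
    bend_e[e_bd] = t_bd
    acc[0] = area_new
    acc[1] = vol_new
    return True


@njit(cache=True)
def _try_particle_move(p, cx, cy, cz, T, pos, adh, ppos, paxis, adh_mask, par, acc, adh_new_col):
    P = ppos.shape[0]
    dp2 = par[13]
    for q in range(P):
        if q == p:
            continue
        dx = ppos[q, 0] - cx
        dy = ppos[q, 1] - cy
        dz = ppos[q, 2] - cz
        if dx * dx + dy * dy + dz * dz < dp2:
            return False
    old = ppos[p, 0], ppos[p, 1], ppos[p, 2]
    ppos[p, 0], ppos[p, 1], ppos[p, 2] = cx, cy, cz
    dE = 0.0
    n = pos.shape[0]
    ok = True
    for v in range(n):
        val = _adh_one(pos[v, 0], pos[v, 1], pos[v, 2], ppos, paxis, p, par)
        if val >= _INF:
            ok = False
            break
        if adh_mask[v, p] == 0:
            val = 0.0
        adh_new_col[v] = val
        dE += val - adh[v, p]
    if not ok:
        ppos[p, 0], ppos[p, 1], ppos[p, 2] = old
        return False
    if dE > 0.0:
        if np.random.random() >= np.exp(-dE / T):
            ppos[p, 0], ppos[p, 1], ppos[p, 2] = old
            return False
    for v in range(n):
        acc[3] += adh_new_col[v] - adh[v, p]
        adh[v, p] = adh_new_col[v]
    return True


@njit(cache=True)
def _try_aspect_move(g, axis, T, pos, faces, edge_v, edge_f,
                     fnormal, farea, fvol6, bend_e, par, acc,
                     L, ncx, head, nxt, vcell,
                     pos2, fnormal2, farea2, fvol62, bend_e2):
    """Volume-preserving global anisotropic scaling (collective shape move).

    The chosen axis is stretched by ``e^g`` and the two others shrunk by
    ``e^{-g/2}``; ``g`` is drawn symmetrically about 0, the map has unit
    phase-space Jacobian, so plain Metropolis acceptance is correct.  This
    samples the slow ellipsoidal shape mode that single-vertex moves take
    very long to traverse.  Only used for particle-free systems.
    """
    V = pos.shape[0]
    su = np.exp(g)
    sv = np.exp(-0.5 * g)
    for v in range(V):
        for k in range(3):
            s = su if k == axis else sv
            pos2[v, k] = pos[v, k] * s
        if abs(pos2[v, 0]) > L - 2.0 or abs(pos2[v, 1]) > L - 2.0 or abs(pos2[v, 2]) > L - 2.0:
            return False
    # tether bounds on every edge
    lmin2 = par[0]
    lmax2 = par[1]
    for e in range(edge_v.shape[0]):
        a, b = edge_v[e, 0], edge_v[e, 1]
        dx = pos2[a, 0] - pos2[b, 0]
        dy = pos2[a, 1] - pos2[b, 1]
        dz = pos2[a, 2] - pos2[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < lmin2 or r2 > lmax2:
            return False
    # hard cores: only pairs already within ~l_min / min-scale can violate
    margin2 = lmin2 * np.exp(2.0 * abs(g)) * 1.0001
    for v in range(V):
        ix = int(np.floor(pos[v, 0] + L))
        iy = int(np.floor(pos[v, 1] + L))
        iz = int(np.floor(pos[v, 2] + L))
        for dxc in range(-1, 2):
            for dyc in range(-1, 2):
                for dzc in range(-1, 2):
                    jx, jy, jz = ix + dxc, iy + dyc, iz + dzc
                    if jx < 0 or jy < 0 or jz < 0 or jx >= ncx or jy >= ncx or jz >= ncx:
                        continue
                    u = head[jx + ncx * (jy + ncx * jz)]
                    while u != -1:
                        if u > v:
                            ddx = pos[u, 0] - pos[v, 0]
                            ddy = pos[u, 1] - pos[v, 1]
                            ddz = pos[u, 2] - pos[v, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < margin2:
                                ex = pos2[u, 0] - pos2[v, 0]
                                ey = pos2[u, 1] - pos2[v, 1]
                                ez = pos2[u, 2] - pos2[v, 2]
                                if ex * ex + ey * ey + ez * ez < lmin2:
                                    return False
                        u = nxt[u]
    # full geometry recompute on the scaled configuration
    F = faces.shape[0]
    area = 0.0
    vol6 = 0.0
    for f in range(F):
        nx, ny, nz, a, v6 = _face_geom(pos2, faces[f, 0], faces[f, 1], faces[f, 2])
        fnormal2[f, 0], fnormal2[f, 1], fnormal2[f, 2] = nx, ny, nz
        farea2[f] = a
        fvol62[f] = v6
        area += a
        vol6 += v6
    eb = 0.0
    for e in range(edge_f.shape[0]):
        f1, f2 = edge_f[e, 0], edge_f[e, 1]
        dot = (fnormal2[f1, 0] * fnormal2[f2, 0] + fnormal2[f1, 1] * fnormal2[f2, 1]
               + fnormal2[f1, 2] * fnormal2[f2, 2])
        bend_e2[e] = par[2] * (1.0 - dot)
        eb += bend_e2[e]
    vol = vol6 / 6.0
    dE = (eb - acc[2]) + _constraint_u(area, vol, par) - _constraint_u(acc[0], acc[1], par)
    if dE > 0.0:
        if np.random.random() >= np.exp(-dE / T):
            return False
    pos[:, :] = pos2
    fnormal[:, :] = fnormal2
    farea[:] = farea2
    fvol6[:] = fvol62
    bend_e[:] = bend_e2
    acc[0] = area
    acc[1] = vol
    acc[2] = eb
    build_cells(pos, L, ncx, head, nxt, vcell)
    return True


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_sweeps(n_sweeps, T, seed,
               pos, faces, face_edges, edge_v, edge_f, vfaces, vnf,
               fnormal, farea, fvol6, bend_e, adh, ppos, paxis, pmob,
               adh_mask, par, acc, L, ncx, head, nxt, vcell,
               flip_fraction, n_aspect, amp_aspect, counters, trace):
    """Run ``n_sweeps`` Metropolis sweeps at temperature ``T``.

    One sweep makes V vertex-move attempts, ``flip_fraction * E`` edge-flip
    attempts and one move attempt per mobile particle, in random interleaved
    order.  ``trace`` (n_sweeps, 4) receives per-sweep
    [area, volume, E_bend, E_adh].  Totals are refreshed from scratch on
    entry to keep float drift out of long runs.
    """
    np.random.seed(seed)
    rebuild(pos, faces, edge_f, fnormal, farea, fvol6, bend_e, adh,
            ppos, paxis, adh_mask, par, acc)
    build_cells(pos, L, ncx, head, nxt, vcell)
    V = pos.shape[0]
    E = edge_v.shape[0]
    P = ppos.shape[0]
    n_mob = 0
    for p in range(P):
        if pmob[p]:
            n_mob += 1
    nflip = int(flip_fraction * E)
    n_att = V + nflip + n_mob
    pv = V / n_att
    pf = (V + nflip) / n_att
    amp_v = par[14]
    amp_p = par[15]
    tmpn = np.empty((MAXDEG, 3))
    tmpa = np.empty(MAXDEG)
    tmpv = np.empty(MAXDEG)
    tmpf = np.empty(MAXDEG, dtype=np.int64)
    eids = np.empty(3 * MAXDEG, dtype=np.int64)
    eterms = np.empty(3 * MAXDEG)
    adh_new = np.empty(max(P, 1))
    adh_new_col = np.empty(V)
    pos2 = np.empty_like(pos)
    fnormal2 = np.empty_like(fnormal)
    farea2 = np.empty_like(farea)
    fvol62 = np.empty_like(fvol6)
    bend_e2 = np.empty_like(bend_e)
    for s in range(n_sweeps):
        for _ in range(n_att):
            r = np.random.random()
            if r < pv:
                v = np.random.randint(0, V)
                px = pos[v, 0] + amp_v * (2.0 * np.random.random() - 1.0)
                py = pos[v, 1] + amp_v * (2.0 * np.random.random() - 1.0)
                pz = pos[v, 2] + amp_v * (2.0 * np.random.random() - 1.0)
                counters[V_MOVE, 0] += 1
                if _try_vertex_move(v, px, py, pz, T, pos, faces, face_edges,
                                    edge_f, vfaces, vnf, fnormal, farea, fvol6,
                                    bend_e, adh, ppos, paxis, adh_mask, par,
                                    acc, L, ncx, head, nxt, vcell, tmpn, tmpa,
                                    tmpv, tmpf, eids, eterms, adh_new):
                    counters[V_MOVE, 1] += 1
            elif r < pf:
                e = np.random.randint(0, E)
                counters[F_MOVE, 0] += 1
                if _try_flip(e, T, pos, faces, face_edges, edge_v, edge_f,
                             vfaces, vnf, fnormal, farea, fvol6, bend_e, par, acc):
                    counters[F_MOVE, 1] += 1
            else:
                if n_mob == 0:
                    continue
                k = np.random.randint(0, n_mob)
                p = -1
                cnt = 0
                for q in range(P):
                    if pmob[q]:
                        if cnt == k:
                            p = q
                            break
                        cnt += 1
                cx = ppos[p, 0] + amp_p * (2.0 * np.random.random() - 1.0)
                cy = ppos[p, 1] + amp_p * (2.0 * np.random.random() - 1.0)
                cz = ppos[p, 2] + amp_p * (2.0 * np.random.random() - 1.0)
                counters[P_MOVE, 0] += 1
                if _try_particle_move(p, cx, cy, cz, T, pos, adh, ppos, paxis,
                                      adh_mask, par, acc, adh_new_col):
                    counters[P_MOVE, 1] += 1
        for _ in range(n_aspect):
            g = amp_aspect * (2.0 * np.random.random() - 1.0)
            axis = np.random.randint(0, 3)
            counters[A_MOVE, 0] += 1
            if _try_aspect_move(g, axis, T, pos, faces, edge_v, edge_f,
                                fnormal, farea, fvol6, bend_e, par, acc,
                                L, ncx, head, nxt, vcell,
                                pos2, fnormal2, farea2, fvol62, bend_e2):
                counters[A_MOVE, 1] += 1
        trace[s, 0] = acc[0]
        trace[s, 1] = acc[1]
        trace[s, 2] = acc[2]
        trace[s, 3] = acc[3]
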