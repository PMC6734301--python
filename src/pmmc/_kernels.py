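"""Compiled numerical kernels.

Everything numerically hot lives here as numba ``njit`` functions operating on
plain arrays: CT-ramp interpolation, the analytic range/stopping model, the
condensed-history micro-step physics (energy loss + straggling, Highland
multiple scattering, simplified elastic/inelastic nuclear interactions), voxel
ray traversal, and the three transport engines (slab pre-simulation, full
reference MC, macro-step transport).

The pre-simulator and the reference engine call the *same* sampling functions
(:func:`sample_energy_loss`, :func:`sample_deflection`, :func:`sigma_inelastic`,
:func:`sigma_elastic`, :func:`sample_inelastic_split`, :func:`sample_elastic`)
so that the slab database and the voxel benchmark share micro-physics by
construction.

Conventions: positions in cm, energies in MeV, directions are unit vectors;
voxel (i, j, k) spans the half-open box [origin + i*d, origin + (i+1)*d).
Deposits go through a stamp/touched-list accumulator so that per-history
voxel totals (for history-by-history variance) cost O(touched voxels).
"""

import math

import numpy as np
from numba import njit

PROTON_MASS = 938.272  # MeV/c^2

# status codes of the polyline walker
WALK_FULL = 0
WALK_TARGET = 1
WALK_BREAK = 2
WALK_EXIT = 3

# particle kinds
KIND_PRIMARY = 0
KIND_SECONDARY = 1
KIND_NEUTRON = 2


# ---------------------------------------------------------------------------
# basic physics
# ---------------------------------------------------------------------------

@njit(cache=True)
def momentum_velocity(energy):
    """p*v [MeV] for a proton of kinetic energy E."""
    et = energy + PROTON_MASS
    return (et * et - PROTON_MASS * PROTON_MASS) / et


@njit(cache=True)
def csda_range_k(a, e):
    return a * e * (e + 2.0)


@njit(cache=True)
def residual_energy_k(a, r):
    if r <= 0.0:
        return 0.0
    return -1.0 + math.sqrt(1.0 + r / a)


@njit(cache=True)
def stopping_power_k(a, e):
    return 1.0 / (a * (2.0 * e + 2.0))


@njit(cache=True)
def highland_sigma_k(e, path, rho, hc, x0w):
    """Highland multiple-scattering polar-angle sigma [rad] over ``path`` cm."""
    t = path * rho / x0w
    if t <= 0.0 or e <= 0.0:
        return 0.0
    th = hc / momentum_velocity(e) * math.sqrt(t) * (1.0 + math.log10(t) / 9.0)
    if th < 0.0:
        th = 0.0
    return th


@njit(cache=True)
def _nuclear_ramp(e, thr):
    # energy dependence of the simplified nuclear cross-sections:
    # flat above 100 MeV, linear to zero at the threshold
    if e <= thr:
        return 0.0
    if e >= 100.0:
        return 1.0
    return (e - thr) / (100.0 - thr)


@njit(cache=True)
def sigma_inelastic(e, rho, xs, thr):
    """Macroscopic inelastic cross-section [1/cm] at density rho."""
    return xs * rho * _nuclear_ramp(e, thr)


@njit(cache=True)
def sigma_elastic(e, rho, xs, thr):
    """Macroscopic elastic cross-section [1/cm] at density rho."""
    return xs * rho * _nuclear_ramp(e, thr)


@njit(cache=True)
def sample_energy_loss(e, a, rho, ds, stopping, straggle_c):
    """Energy loss over a micro step: closed-form mean plus Bohr straggling.

    The Gaussian fluctuation is truncated to a window symmetric about the
    mean (so truncation cannot bias the mean) that also keeps the loss
    within [0, e]."""
    if stopping:
        return e
    r = csda_range_k(a, e)
    de = e - residual_energy_k(a, r - ds)
    sg = math.sqrt(straggle_c * rho * ds)
    lim = 3.5 * sg
    if de < lim:
        lim = de
    if e - de < lim:
        lim = e - de
    if lim < 0.0:
        lim = 0.0
    delta = sg * np.random.normal(0.0, 1.0)
    if delta > lim:
        delta = lim
    elif delta < -lim:
        delta = -lim
    return de + delta


@njit(cache=True)
def _highland_var_t(e, t, hc, x0w):
    # squared Highland angle as a function of cumulative radiation-length path
    if t <= 0.0:
        return 0.0
    f = hc / momentum_velocity(e) * math.sqrt(t) * (1.0 + math.log10(t) / 9.0)
    return f * f


@njit(cache=True)
def sample_deflection(e, rho, ds, t_cum, hc, x0w):
    """Multiple-scattering kick: (polar angle, azimuth, new cumulative t).

    The per-step variance telescopes on the cumulative radiation-length path
    so that the summed scattering variance reproduces the Highland formula
    for the full traversed path (exactly so at constant energy).
    """
    t_new = t_cum + ds * rho / x0w
    var = _highland_var_t(e, t_new, hc, x0w) - _highland_var_t(e, t_cum, hc, x0w)
    if var < 0.0:
        var = 0.0
    th0 = math.sqrt(var)
    u = np.random.random()
    if u < 1e-300:
        u = 1e-300
    th = th0 * math.sqrt(-2.0 * math.log(u))
    phi = 2.0 * math.pi * np.random.random()
    return th, phi, t_new



@njit(cache=True)
def _highland_g(x):
    # g(t) = t * (1 + log10(t)/9)^2, the Highland variance shape
    if x <= 0.0:
        return 0.0
    c = 1.0 / (9.0 * math.log(10.0))
    f = 1.0 + c * math.log(x)
    return x * f * f


@njit(cache=True)
def _highland_g_int(x):
    # closed-form integral of _highland_g from 0 to x
    if x <= 0.0:
        return 0.0
    c = 1.0 / (9.0 * math.log(10.0))
    f = 1.0 + c * math.log(x)
    return 0.5 * x * x * (f * f - c * f + 0.5 * c * c)


@njit(cache=True)
def sample_elastic(e, elastic_angle_mev, recoil_fraction):
    """Elastic scatter: (polar deflection, azimuth, recoil energy deposit)."""
    sg = elastic_angle_mev / momentum_velocity(e)
    u = np.random.random()
    if u < 1e-300:
        u = 1e-300
    th = sg * math.sqrt(-2.0 * math.log(u))
    if th > 1.4:
        th = 1.4
    phi = 2.0 * math.pi * np.random.random()
    return th, phi, recoil_fraction * e


@njit(cache=True)
def sample_inelastic_split(e_avail, neutron_fraction, sec_angle_sigma):
    """Inelastic event: (E secondary proton, theta, phi, E neutron, E local)."""
    f = 0.3 + 0.5 * np.random.random()  # mean 0.55 of available energy
    ep = f * e_avail
    en = neutron_fraction * e_avail
    elocal = e_avail - ep - en
    if elocal < 0.0:
        elocal = 0.0
    u = np.random.random()
    if u < 1e-300:
        u = 1e-300
    th = sec_angle_sigma * math.sqrt(-2.0 * math.log(u))
    if th > 1.4:
        th = 1.4
    phi = 2.0 * math.pi * np.random.random()
    return ep, th, phi, en, elocal


@njit(cache=True)
def rotate_direction(ux, uy, uz, th, phi):
    """Rotate unit vector u by polar angle th about itself, azimuth phi."""
    st = math.sin(th)
    ct = math.cos(th)
    # orthonormal basis perpendicular to u
    if abs(uz) < 0.9:
        n = math.sqrt(ux * ux + uy * uy)
        e1x, e1y, e1z = uy / n, -ux / n, 0.0
    else:
        n = math.sqrt(uy * uy + uz * uz)
        e1x, e1y, e1z = 0.0, uz / n, -uy / n
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    cp = math.cos(phi)
    sp = math.sin(phi)
    vx = ct * ux + st * (cp * e1x + sp * e2x)
    vy = ct * uy + st * (cp * e1y + sp * e2y)
    vz = ct * uz + st * (cp * e1z + sp * e2z)
    inv = 1.0 / math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx * inv, vy * inv, vz * inv


# ---------------------------------------------------------------------------
# CT ramp lookups
# ---------------------------------------------------------------------------

@njit(cache=True)
def ramp_interp(hu, nodes, vals):
    """Clamped piecewise-linear interpolation of a per-node property."""
    n = nodes.size
    if hu <= nodes[0]:
        return vals[0]
    if hu >= nodes[n - 1]:
        return vals[n - 1]
    for i in range(n - 1):
        if hu <= nodes[i + 1]:
            w = (hu - nodes[i]) / (nodes[i + 1] - nodes[i])
            return vals[i] + w * (vals[i + 1] - vals[i])
    return vals[n - 1]


@njit(cache=True)
def band_lower_node(hu, nodes):
    """Index b with hu in [node_b, node_{b+1}], clamped to the ramp."""
    n = nodes.size
    if hu <= nodes[0]:
        return 0
    if hu >= nodes[n - 2]:
        return n - 2
    b = 0
    for i in range(n - 1):
        if hu >= nodes[i]:
            b = i
        else:
            break
    return b


@njit(cache=True)
def is_interface_k(hu_a, hu_b, nodes):
    """True iff a ramp node lies strictly between the (clamped) HU values."""
    n = nodes.size
    a = min(max(hu_a, nodes[0]), nodes[n - 1])
    b = min(max(hu_b, nodes[0]), nodes[n - 1])
    lo = min(a, b)
    hi = max(a, b)
    for i in range(n):
        if lo < nodes[i] < hi:
            return True
    return False


# ---------------------------------------------------------------------------
# voxel grid traversal
# ---------------------------------------------------------------------------

@njit(cache=True)
def _clip_to_grid(px, py, pz, ux, uy, uz, length,
                  ox, oy, oz, lx, ly, lz):
    """Intersect segment [p, p + length*u] with the grid box.

    Returns (t0, t1) in cm along the segment; t0 > t1 means no overlap.
    """
    t0 = 0.0
    t1 = length
    # x slabs
    for axis in range(3):
        if axis == 0:
            p, u, lo, hi = px, ux, ox, ox + lx
        elif axis == 1:
            p, u, lo, hi = py, uy, oy, oy + ly
        else:
            p, u, lo, hi = pz, uz, oz, oz + lz
        if abs(u) < 1e-14:
            if p < lo or p >= hi:
                return 1.0, 0.0
        else:
            ta = (lo - p) / u
            tb = (hi - p) / u
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
            if t0 > t1:
                return 1.0, 0.0
    return t0, t1


@njit(cache=True)
def walk_segment(hu, nodes, ox, oy, oz, dx, dy, dz,
                 px, py, pz, ux, uy, uz, length,
                 target_len, hu_ref, break_mode,
                 seg_vox, seg_len, seg_t0, nseg,
                 len_offset):
    """March a straight segment through the grid, appending voxel cuts.

    ``target_len`` is the remaining track length to walk (cm, measured along
    the full polyline; ``len_offset`` has been consumed on earlier legs).
    ``break_mode``: 0 = never break, 1 = break on band interface w.r.t.
    ``hu_ref``, 2 = break on any HU difference w.r.t. ``hu_ref``.

    Appends (linear voxel index, cut length, entry-t) to the buffers starting
    at ``nseg``.  Returns (nseg, consumed_len_on_this_leg, status, sx, sy, sz)
    where (sx, sy, sz) is the stop point.
    """
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    want = length
    hit_target = False
    if target_len - len_offset < want:
        want = target_len - len_offset
        hit_target = True
    if want <= 0.0:
        return nseg, 0.0, WALK_TARGET, px, py, pz

    t0, t1 = _clip_to_grid(px, py, pz, ux, uy, uz, want,
                           ox, oy, oz, nx * dx, ny * dy, nz * dz)
    if t0 > t1:
        # no in-grid portion on this leg
        status = WALK_TARGET if hit_target else WALK_FULL
        return nseg, want, status, px + want * ux, py + want * uy, pz + want * uz

    eps = 1e-9 * (1.0 + abs(want))
    t = t0
    qx = px + (t0 + eps) * ux
    qy = py + (t0 + eps) * uy
    qz = pz + (t0 + eps) * uz
    i = int(math.floor((qx - ox) / dx))
    j = int(math.floor((qy - oy) / dy))
    k = int(math.floor((qz - oz) / dz))
    if i < 0:
        i = 0
    elif i >= nx:
        i = nx - 1
    if j < 0:
        j = 0
    elif j >= ny:
        j = ny - 1
    if k < 0:
        k = 0
    elif k >= nz:
        k = nz - 1

    # per-axis next-boundary crossing parameters
    if ux > 0.0:
        tx = ((i + 1) * dx + ox - px) / ux
        stepi, dtx = 1, dx / ux
    elif ux < 0.0:
        tx = (i * dx + ox - px) / ux
        stepi, dtx = -1, -dx / ux
    else:
        tx, stepi, dtx = 1e30, 0, 1e30
    if uy > 0.0:
        ty = ((j + 1) * dy + oy - py) / uy
        stepj, dty = 1, dy / uy
    elif uy < 0.0:
        ty = (j * dy + oy - py) / uy
        stepj, dty = -1, -dy / uy
    else:
        ty, stepj, dty = 1e30, 0, 1e30
    if uz > 0.0:
        tz = ((k + 1) * dz + oz - pz) / uz
        stepk, dtz = 1, dz / uz
    elif uz < 0.0:
        tz = (k * dz + oz - pz) / uz
        stepk, dtz = -1, -dz / uz
    else:
        tz, stepk, dtz = 1e30, 0, 1e30

    first = True
    while t < t1 - 1e-12:
        # environment-breaking check on entry to each voxel
        if break_mode != 0 and not first:
            hv = hu[i, j, k]
            if break_mode == 1:
                if is_interface_k(hu_ref, hv, nodes):
                    return nseg, t, WALK_BREAK, px + t * ux, py + t * uy, pz + t * uz
            else:
                if hv != hu_ref:
                    return nseg, t, WALK_BREAK, px + t * ux, py + t * uy, pz + t * uz
        first = False
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn > t1:
            tn = t1
        cut = tn - t
        if cut > 1e-12:
            seg_vox[nseg] = (i * ny + j) * nz + k
            seg_len[nseg] = cut
            seg_t0[nseg] = len_offset + t
            nseg += 1
        t = tn
        if t >= t1 - 1e-12:
            break
        if tx <= ty and tx <= tz:
            i += stepi
            tx += dtx
            if i < 0 or i >= nx:
                return nseg, t, WALK_EXIT, px + t * ux, py + t * uy, pz + t * uz
        elif ty <= tz:
            j += stepj
            ty += dty
            if j < 0 or j >= ny:
                return nseg, t, WALK_EXIT, px + t * ux, py + t * uy, pz + t * uz
        else:
            k += stepk
            tz += dtz
            if k < 0 or k >= nz:
                return nseg, t, WALK_EXIT, px + t * ux, py + t * uy, pz + t * uz

    if t1 < want - 1e-12:
        # left the grid before the end of the leg
        return nseg, t1, WALK_EXIT, px + t1 * ux, py + t1 * uy, pz + t1 * uz
    status = WALK_TARGET if hit_target else WALK_FULL
    return nseg, want, status, px + want * ux, py + want * uy, pz + want * uz


@njit(cache=True)
def distance_to_interface_k(hu, nodes, ox, oy, oz, dx, dy, dz,
                            px, py, pz, ux, uy, uz, max_d, any_hu_change):
    """Distance along the ray to the first voxel boundary whose two adjacent
    voxels are band-separated (or differ at all if ``any_hu_change``), capped
    at min(max_d, distance to grid exit)."""
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    i = int(math.floor((px - ox) / dx))
    j = int(math.floor((py - oy) / dy))
    k = int(math.floor((pz - oz) / dz))
    if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
        return -1.0  # caller raises out-of-grid

    if ux > 0.0:
        tx = ((i + 1) * dx + ox - px) / ux
        stepi, dtx = 1, dx / ux
    elif ux < 0.0:
        tx = (i * dx + ox - px) / ux
        stepi, dtx = -1, -dx / ux
    else:
        tx, stepi, dtx = 1e30, 0, 1e30
    if uy > 0.0:
        ty = ((j + 1) * dy + oy - py) / uy
        stepj, dty = 1, dy / uy
    elif uy < 0.0:
        ty = (j * dy + oy - py) / uy
        stepj, dty = -1, -dy / uy
    else:
        ty, stepj, dty = 1e30, 0, 1e30
    if uz > 0.0:
        tz = ((k + 1) * dz + oz - pz) / uz
        stepk, dtz = 1, dz / uz
    elif uz < 0.0:
        tz = (k * dz + oz - pz) / uz
        stepk, dtz = -1, -dz / uz
    else:
        tz, stepk, dtz = 1e30, 0, 1e30

    hu_prev = hu[i, j, k]
    t = 0.0
    while True:
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn >= max_d:
            return max_d
        if tx <= ty and tx <= tz:
            i += stepi
            tx += dtx
        elif ty <= tz:
            j += stepj
            ty += dty
        else:
            k += stepk
            tz += dtz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return tn  # grid exit
        hv = hu[i, j, k]
        if any_hu_change:
            if hv != hu_prev:
                return tn
        else:
            if is_interface_k(hu_prev, hv, nodes):
                return tn
        hu_prev = hv
        t = tn


@njit(cache=True)
def lateral_interface_distance_k(hu, nodes, ox, oy, oz, dx, dy, dz,
                                 px, py, pz, ux, uy, uz,
                                 step_len, radius):
    """Minimum distance from the step segment to any voxel whose material band
    differs from the origin voxel's, searched within ``radius`` (cylinder test
    sampled at half the smallest voxel pitch).  Returns ``radius`` if none."""
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    i0 = int(math.floor((px - ox) / dx))
    j0 = int(math.floor((py - oy) / dy))
    k0 = int(math.floor((pz - oz) / dz))
    if i0 < 0 or i0 >= nx or j0 < 0 or j0 >= ny or k0 < 0 or k0 >= nz:
        return radius
    hu0 = hu[i0, j0, k0]

    ds = 0.5 * min(dx, min(dy, dz))
    nsmp = int(step_len / ds) + 1
    mi = int(radius / dx) + 1
    mj = int(radius / dy) + 1
    mk = int(radius / dz) + 1
    best = radius
    for s in range(nsmp + 1):
        tt = s * ds
        if tt > step_len:
            tt = step_len
        qx = px + tt * ux
        qy = py + tt * uy
        qz = pz + tt * uz
        ci = int(math.floor((qx - ox) / dx))
        cj = int(math.floor((qy - oy) / dy))
        ck = int(math.floor((qz - oz) / dz))
        for ii in range(ci - mi, ci + mi + 1):
            if ii < 0 or ii >= nx:
                continue
            for jj in range(cj - mj, cj + mj + 1):
                if jj < 0 or jj >= ny:
                    continue
                for kk in range(ck - mk, ck + mk + 1):
                    if kk < 0 or kk >= nz:
                        continue
                    if not is_interface_k(hu0, hu[ii, jj, kk], nodes):
                        continue
                    # point-to-box distance
                    bx0 = ox + ii * dx
                    by0 = oy + jj * dy
                    bz0 = oz + kk * dz
                    ex = 0.0
                    if qx < bx0:
                        ex = bx0 - qx
                    elif qx > bx0 + dx:
                        ex = qx - (bx0 + dx)
                    ey = 0.0
                    if qy < by0:
                        ey = by0 - qy
                    elif qy > by0 + dy:
                        ey = qy - (by0 + dy)
                    ez = 0.0
                    if qz < bz0:
                        ez = bz0 - qz
                    elif qz > bz0 + dz:
                        ez = qz - (bz0 + dz)
                    d = math.sqrt(ex * ex + ey * ey + ez * ez)
                    if d < best:
                        best = d
        if best <= 0.0:
            return 0.0
    return best


# ---------------------------------------------------------------------------
# dose accumulation (stamp / touched-list scheme)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dep(cur, stamp, touched, cnt, h, v, e, hsum):
    """Add ``e`` to voxel v for history h; returns updated touched count."""
    if stamp[v] == h:
        cur[v] += e
        return cnt
    if cnt >= touched.size:
        # touched-list overflow: account the energy but skip variance tracking
        hsum[v] += e
        return cnt
    stamp[v] = h
    cur[v] = e
    touched[cnt] = v
    return cnt + 1


@njit(cache=True)
def _flush(cur, touched, cnt, hsum, hsumsq, batch, b):
    """Fold one history's per-voxel totals into the run accumulators."""
    tot = 0.0
    for t in range(cnt):
        v = touched[t]
        val = cur[v]
        hsum[v] += val
        hsumsq[v] += val * val
        batch[b, v] += val
        tot += val
    return tot


# ---------------------------------------------------------------------------
# energy deposition kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def spa_deposit_k(seg_vox, seg_len, seg_rm, nseg, de, e0,
                  scratch, cur, stamp, touched, cnt, h, hsum):
    """Distribute ``de`` over track segments with a linear stopping-power
    profile weighted by local rho*mSPR; renormalized to conserve ``de``.

    ``e0`` is the proton kinetic energy at the start of the macro step.
    Returns the updated touched count.
    """
    if de <= 0.0 or nseg == 0:
        return cnt
    dtr = 0.0
    rmsum = 0.0
    for s in range(nseg):
        dtr += seg_len[s]
        rmsum += seg_len[s] * seg_rm[s]
    if dtr <= 1e-12:
        return _dep(cur, stamp, touched, cnt, h, seg_vox[0], de, hsum)
    shat = de / dtr
    rmhat = rmsum / dtr
    denom = e0 - 0.5 * de
    if denom > 1e-9:
        grad = 0.8 * (shat * shat - 4.0 * rmhat * rmhat) / denom
    else:
        grad = 0.0
    s00 = shat - 0.5 * dtr * grad
    if s00 < 0.0:
        # clamp: keep the mean by re-fitting the slope (S runs 0 -> 2*shat)
        s00 = 0.0
        grad = 2.0 * shat / dtr
    elif s00 + dtr * grad < 0.0:
        s00 = 2.0 * shat
        grad = -2.0 * shat / dtr
    s0 = s00
    tot = 0.0
    for s in range(nseg):
        s1 = s0 + seg_len[s] * grad
        ei = seg_len[s] * 0.5 * (s0 + s1) * seg_rm[s] / rmhat
        if ei < 0.0:
            ei = 0.0
        scratch[s] = ei
        tot += ei
        s0 = s1
    if tot <= 0.0:
        # degenerate profile: fall back to path-length weighting
        for s in range(nseg):
            scratch[s] = seg_len[s] * seg_rm[s]
            tot += scratch[s]
    scale = de / tot
    for s in range(nseg):
        cnt = _dep(cur, stamp, touched, cnt, h, seg_vox[s], scratch[s] * scale, hsum)
    return cnt


@njit(cache=True)
def csda_deposit_k(hu, nodes, dens, msprs, acss,
                   ox, oy, oz, dx, dy, dz,
                   px, py, pz, ux, uy, uz, e,
                   cur, stamp, touched, cnt, h, hsum):
    """Deposit the full remaining energy along the ray by residual-range
    book-keeping; returns (cnt, escaped_energy)."""
    if e <= 0.0:
        return cnt, 0.0
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    i = int(math.floor((px - ox) / dx))
    j = int(math.floor((py - oy) / dy))
    k = int(math.floor((pz - oz) / dz))
    if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
        return cnt, e
    hu0 = np.float64(hu[i, j, k])
    a0 = ramp_interp(hu0, nodes, acss)
    rm0 = ramp_interp(hu0, nodes, dens) * ramp_interp(hu0, nodes, msprs)
    rng = csda_range_k(a0, e)
    eprev = e

    if ux > 0.0:
        tx = ((i + 1) * dx + ox - px) / ux
        stepi, dtx = 1, dx / ux
    elif ux < 0.0:
        tx = (i * dx + ox - px) / ux
        stepi, dtx = -1, -dx / ux
    else:
        tx, stepi, dtx = 1e30, 0, 1e30
    if uy > 0.0:
        ty = ((j + 1) * dy + oy - py) / uy
        stepj, dty = 1, dy / uy
    elif uy < 0.0:
        ty = (j * dy + oy - py) / uy
        stepj, dty = -1, -dy / uy
    else:
        ty, stepj, dty = 1e30, 0, 1e30
    if uz > 0.0:
        tz = ((k + 1) * dz + oz - pz) / uz
        stepk, dtz = 1, dz / uz
    elif uz < 0.0:
        tz = (k * dz + oz - pz) / uz
        stepk, dtz = -1, -dz / uz
    else:
        tz, stepk, dtz = 1e30, 0, 1e30

    t = 0.0
    while True:
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        cut = tn - t
        hv = np.float64(hu[i, j, k])
        rm = ramp_interp(hv, nodes, dens) * ramp_interp(hv, nodes, msprs)
        dr = cut * rm / rm0
        v = (i * ny + j) * nz + k
        if dr >= rng:
            cnt = _dep(cur, stamp, touched, cnt, h, v, eprev, hsum)
            return cnt, 0.0
        rng -= dr
        enew = residual_energy_k(a0, rng)
        cnt = _dep(cur, stamp, touched, cnt, h, v, eprev - enew, hsum)
        eprev = enew
        t = tn
        if tx <= ty and tx <= tz:
            i += stepi
            tx += dtx
        elif ty <= tz:
            j += stepj
            ty += dty
        else:
            k += stepk
            tz += dtz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return cnt, eprev


# ---------------------------------------------------------------------------
# slab pre-simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def simulate_slab_k(a, rho, rho_sc, thickness, e0, seeds, micro,
                    straggle_c, hc, x0w, xs_inel, xs_el, nuc_thr, stop_e,
                    out_de, out_th, out_disp, out_stopped,
                    depth_el, depth_inel):
    """Condensed-history transport through a homogeneous slab.

    Hard interactions are accumulated analytically (survival-weighted) into
    the depth histograms instead of being sampled, which gives low-variance
    interaction probabilities while the kinematic histograms describe
    interaction-free traversal.
    """
    n = seeds.size
    nd = depth_el.size
    for hist in range(n):
        np.random.seed(seeds[hist])
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        e = e0
        surv = 1.0
        t_cum = 0.0
        while True:
            if uz <= 1e-6:
                # (rare) backscatter out of the slab: book as stopped
                out_de[hist] = e0
                out_th[hist] = math.acos(max(min(uz, 1.0), -1.0))
                out_disp[hist] = math.sqrt(x * x + y * y)
                out_stopped[hist] = 1
                break
            ds = micro
            exiting = False
            dz_exit = (thickness - z) / uz
            if ds >= dz_exit:
                ds = dz_exit
                exiting = True
            stopping = False
            r = csda_range_k(a, e)
            if r <= ds:
                ds = r
                stopping = True
                exiting = False
            # analytic interaction accumulation at pre-step energy
            si = sigma_inelastic(e, rho, xs_inel, nuc_thr)
            se = sigma_elastic(e, rho, xs_el, nuc_thr)
            stot = si + se
            if stot > 0.0:
                p = 1.0 - math.exp(-stot * ds)
                zmid = z + uz * ds * 0.5
                bi = int(zmid / thickness * nd)
                if bi >= nd:
                    bi = nd - 1
                depth_inel[bi] += surv * p * si / stot
                depth_el[bi] += surv * p * se / stot
                surv *= 1.0 - p
            de = sample_energy_loss(e, a, rho, ds, stopping, straggle_c)
            x += ux * ds
            y += uy * ds
            z += uz * ds
            e -= de
            if stopping or e <= stop_e:
                out_de[hist] = e0
                out_th[hist] = math.acos(max(min(uz, 1.0), -1.0))
                out_disp[hist] = math.sqrt(x * x + y * y)
                out_stopped[hist] = 1
                break
            if exiting:
                out_de[hist] = e0 - e
                out_th[hist] = math.acos(max(min(uz, 1.0), -1.0))
                out_disp[hist] = math.sqrt(x * x + y * y)
                out_stopped[hist] = 0
                break
            th, phi, t_cum = sample_deflection(e, rho_sc, ds, t_cum, hc, x0w)
            ux, uy, uz = rotate_direction(ux, uy, uz, th, phi)


# ---------------------------------------------------------------------------
# full reference MC on the voxel grid
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_reference_k(hu, nodes, dens, msprs, acss, scats,
                    ox, oy, oz, dx, dy, dz,
                    entries, dirs, e0, seeds, micro,
                    straggle_c, hc, x0w, xs_inel, xs_el, nuc_thr, stop_e,
                    neutron_fraction, sec_angle_sigma,
                    elastic_angle_mev, recoil_fraction,
                    cur, stamp, touched, hsum, hsumsq, batch,
                    dep_out, esc_out, steps_out):
    """Micro-step condensed-history transport of all histories on the grid."""
    n = seeds.size
    nbatch = batch.shape[0]
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    smax = 64
    st_px = np.empty(smax)
    st_py = np.empty(smax)
    st_pz = np.empty(smax)
    st_ux = np.empty(smax)
    st_uy = np.empty(smax)
    st_uz = np.empty(smax)
    st_e = np.empty(smax)
    for hist in range(n):
        np.random.seed(seeds[hist])
        b = hist * nbatch // n
        cnt = 0
        esc = 0.0
        nsteps = 0
        sp = 0
        st_px[sp] = entries[hist, 0]
        st_py[sp] = entries[hist, 1]
        st_pz[sp] = entries[hist, 2]
        st_ux[sp] = dirs[hist, 0]
        st_uy[sp] = dirs[hist, 1]
        st_uz[sp] = dirs[hist, 2]
        st_e[sp] = e0
        sp = 1
        while sp > 0:
            sp -= 1
            px = st_px[sp]
            py = st_py[sp]
            pz = st_pz[sp]
            ux = st_ux[sp]
            uy = st_uy[sp]
            uz = st_uz[sp]
            e = st_e[sp]
            t_cum = 0.0
            while True:
                i = int(math.floor((px - ox) / dx))
                j = int(math.floor((py - oy) / dy))
                k = int(math.floor((pz - oz) / dz))
                if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                    esc += e
                    break
                v = (i * ny + j) * nz + k
                if e <= stop_e:
                    cnt = _dep(cur, stamp, touched, cnt, hist, v, e, hsum)
                    break
                hv = np.float64(hu[i, j, k])
                rho = ramp_interp(hv, nodes, dens)
                rho_sc = rho * ramp_interp(hv, nodes, scats)
                a = ramp_interp(hv, nodes, acss)
                ds = micro
                stopping = False
                r = csda_range_k(a, e)
                if r <= ds:
                    ds = r
                    stopping = True
                si = sigma_inelastic(e, rho, xs_inel, nuc_thr)
                se = sigma_elastic(e, rho, xs_el, nuc_thr)
                u01 = np.random.random()
                de = sample_energy_loss(e, a, rho, ds, stopping, straggle_c)
                # deposit at the micro-step midpoint voxel
                mx = px + ux * ds * 0.5
                my = py + uy * ds * 0.5
                mz = pz + uz * ds * 0.5
                mi = int(math.floor((mx - ox) / dx))
                mj = int(math.floor((my - oy) / dy))
                mk = int(math.floor((mz - oz) / dz))
                if 0 <= mi < nx and 0 <= mj < ny and 0 <= mk < nz:
                    mv = (mi * ny + mj) * nz + mk
                    cnt = _dep(cur, stamp, touched, cnt, hist, mv, de, hsum)
                else:
                    esc += de
                px += ux * ds
                py += uy * ds
                pz += uz * ds
                e -= de
                nsteps += 1
                if stopping or e <= stop_e:
                    ri = int(math.floor((px - ox) / dx))
                    rj = int(math.floor((py - oy) / dy))
                    rk = int(math.floor((pz - oz) / dz))
                    if 0 <= ri < nx and 0 <= rj < ny and 0 <= rk < nz:
                        rv = (ri * ny + rj) * nz + rk
                        cnt = _dep(cur, stamp, touched, cnt, hist, rv, e, hsum)
                    else:
                        esc += e
                    e = 0.0
                    break
                th, phi, t_cum = sample_deflection(e, rho_sc, ds, t_cum, hc, x0w)
                ux, uy, uz = rotate_direction(ux, uy, uz, th, phi)
                # nuclear interactions at the end of the step
                if u01 < si * ds:
                    ep, sth, sphi, en, elocal = sample_inelastic_split(
                        e, neutron_fraction, sec_angle_sigma)
                    ri = int(math.floor((px - ox) / dx))
                    rj = int(math.floor((py - oy) / dy))
                    rk = int(math.floor((pz - oz) / dz))
                    if 0 <= ri < nx and 0 <= rj < ny and 0 <= rk < nz:
                        rv = (ri * ny + rj) * nz + rk
                        cnt = _dep(cur, stamp, touched, cnt, hist, rv, elocal, hsum)
                    else:
                        esc += elocal
                    esc += en
                    if ep > 0.0:
                        if sp < smax:
                            sx, sy, sz = rotate_direction(ux, uy, uz, sth, sphi)
                            st_px[sp] = px
                            st_py[sp] = py
                            st_pz[sp] = pz
                            st_ux[sp] = sx
                            st_uy[sp] = sy
                            st_uz[sp] = sz
                            st_e[sp] = ep
                            sp += 1
                        else:
                            if 0 <= ri < nx and 0 <= rj < ny and 0 <= rk < nz:
                                rv = (ri * ny + rj) * nz + rk
                                cnt = _dep(cur, stamp, touched, cnt, hist, rv, ep, hsum)
                            else:
                                esc += ep
                    e = 0.0
                    break
                elif u01 < (si + se) * ds:
                    eth, ephi, rec = sample_elastic(e, elastic_angle_mev, recoil_fraction)
                    ri = int(math.floor((px - ox) / dx))
                    rj = int(math.floor((py - oy) / dy))
                    rk = int(math.floor((pz - oz) / dz))
                    if 0 <= ri < nx and 0 <= rj < ny and 0 <= rk < nz:
                        rv = (ri * ny + rj) * nz + rk
                        cnt = _dep(cur, stamp, touched, cnt, hist, rv, rec, hsum)
                    else:
                        esc += rec
                    e -= rec
                    ux, uy, uz = rotate_direction(ux, uy, uz, eth, ephi)
        dep_out[hist] = _flush(cur, touched, cnt, hsum, hsumsq, batch, b)
        esc_out[hist] = esc
        steps_out[hist] = nsteps


# ---------------------------------------------------------------------------
# macro Monte Carlo transport
# ---------------------------------------------------------------------------


@njit(cache=True)
def segment_mean_props(hu, nodes, dens, msprs, acss, scats,
                       ox, oy, oz, dx, dy, dz,
                       px, py, pz, ux, uy, uz, length):
    """Length-weighted mean (HU, density, a_csda) along a straight segment.

    Out-of-grid portions keep the entry-voxel values.  Used to represent the
    material content of a whole macro step rather than its entry voxel only
    (HU varies voxel-by-voxel inside one mixed-material band)."""
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    i = int(math.floor((px - ox) / dx))
    j = int(math.floor((py - oy) / dy))
    k = int(math.floor((pz - oz) / dz))
    hu0 = np.float64(hu[i, j, k])
    if ux > 0.0:
        tx = ((i + 1) * dx + ox - px) / ux
        stepi, dtx = 1, dx / ux
    elif ux < 0.0:
        tx = (i * dx + ox - px) / ux
        stepi, dtx = -1, -dx / ux
    else:
        tx, stepi, dtx = 1e30, 0, 1e30
    if uy > 0.0:
        ty = ((j + 1) * dy + oy - py) / uy
        stepj, dty = 1, dy / uy
    elif uy < 0.0:
        ty = (j * dy + oy - py) / uy
        stepj, dty = -1, -dy / uy
    else:
        ty, stepj, dty = 1e30, 0, 1e30
    if uz > 0.0:
        tz = ((k + 1) * dz + oz - pz) / uz
        stepk, dtz = 1, dz / uz
    elif uz < 0.0:
        tz = (k * dz + oz - pz) / uz
        stepk, dtz = -1, -dz / uz
    else:
        tz, stepk, dtz = 1e30, 0, 1e30
    t = 0.0
    s_hu = 0.0
    s_rho = 0.0
    s_rsc = 0.0
    s_inva = 0.0
    while t < length - 1e-12:
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn > length:
            tn = length
        hv = np.float64(hu[i, j, k])
        cut = tn - t
        s_hu += cut * hv
        rr2 = ramp_interp(hv, nodes, dens)
        s_rho += cut * rr2
        s_rsc += cut * rr2 * ramp_interp(hv, nodes, scats)
        # harmonic average: stopping powers (~1/a) add along the path
        s_inva += cut / ramp_interp(hv, nodes, acss)
        t = tn
        if t >= length - 1e-12:
            break
        if tx <= ty and tx <= tz:
            i += stepi
            tx += dtx
        elif ty <= tz:
            j += stepj
            ty += dty
        else:
            k += stepk
            tz += dtz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            break
    if t < length:
        rem = length - t
        s_hu += rem * hu0
        rr2 = ramp_interp(hu0, nodes, dens)
        s_rho += rem * rr2
        s_rsc += rem * rr2 * ramp_interp(hu0, nodes, scats)
        s_inva += rem / ramp_interp(hu0, nodes, acss)
    inv = 1.0 / length
    return s_hu * inv, s_rho * inv, s_rsc * inv, length / s_inva


@njit(cache=True)
def _choose_slab_idx(avail, tvals, d, lateral, lateral_thr, smallest_idx):
    """Adaptive slab choice: smallest available below the lateral threshold,
    otherwise nearest |t - d| with ties toward the smaller slab.
    Returns -1 when nothing is available."""
    nt = tvals.size
    if lateral < lateral_thr:
        for j in range(nt):
            if avail[j]:
                return j
        return smallest_idx
    best = -1
    bestd = 1e30
    for j in range(nt):
        if avail[j]:
            dd = abs(tvals[j] - d)
            if dd < bestd - 1e-12:
                bestd = dd
                best = j
    if best < 0:
        return smallest_idx
    return best


@njit(cache=True)
def _sample_cdf(cdf, lo, hi):
    """Sample from a binned distribution, uniform within the chosen bin."""
    nb = cdf.size - 1
    u = np.random.random()
    k = np.searchsorted(cdf, u) - 1
    if k < 0:
        k = 0
    elif k >= nb:
        k = nb - 1
    w = cdf[k + 1] - cdf[k]
    frac = (u - cdf[k]) / w if w > 0.0 else np.random.random()
    if frac < 0.0:
        frac = 0.0
    elif frac > 1.0:
        frac = 1.0
    return lo + (hi - lo) * (k + frac) / nb


@njit(cache=True)
def _sample_joint(cdf, na, ndp, th_hi, disp_hi):
    """Sample (angle, displacement) from the flattened joint histogram."""
    u = np.random.random()
    k = np.searchsorted(cdf, u) - 1
    nb = na * ndp
    if k < 0:
        k = 0
    elif k >= nb:
        k = nb - 1
    ia = k // ndp
    idp = k % ndp
    th = th_hi * (ia + np.random.random()) / na
    dp = disp_hi * (idp + np.random.random()) / ndp
    return th, dp


@njit(cache=True)
def run_pmmc_k(hu, nodes, dens, msprs, acss, scats,
               ox, oy, oz, dx, dy, dz,
               entries, dirs, e0, seeds,
               # packed database tables
               avail, tvals, evals,
               de_cdf, de_lo, de_hi, de_mean,
               ex_cdf, th_hi, disp_hi, n_angle, n_disp,
               p_el, p_inel, dep_cdf,
               e_min,
               # physics config (shared with presim/reference)
               hc, x0w, xs_inel, xs_el, nuc_thr,
               neutron_fraction, sec_angle_sigma,
               elastic_angle_mev, recoil_fraction,
               # transport config
               hinge_fraction, lateral_thr, lateral_radius,
               azimuth_sigma, mode_non_adaptive, lateral_enabled,
               use_closed_partial,
               cur, stamp, touched, hsum, hsumsq, batch,
               dep_out, esc_out, steps_out):
    """Macro-step transport of all histories (the pMMC global simulation)."""
    n = seeds.size
    nbatch = batch.shape[0]
    nx = hu.shape[0]
    ny = hu.shape[1]
    nz = hu.shape[2]
    nt = tvals.size
    ne = evals.size
    t_max = tvals[nt - 1]

    segcap = 8192
    seg_vox = np.empty(segcap, dtype=np.int64)
    seg_len = np.empty(segcap)
    seg_t0 = np.empty(segcap)
    seg_rm = np.empty(segcap)
    scratch = np.empty(segcap)
    avail_j = np.empty(nt, dtype=np.uint8)

    smax = 64
    st_px = np.empty(smax)
    st_py = np.empty(smax)
    st_pz = np.empty(smax)
    st_ux = np.empty(smax)
    st_uy = np.empty(smax)
    st_uz = np.empty(smax)
    st_e = np.empty(smax)
    st_t = np.empty(smax)

    for hist in range(n):
        np.random.seed(seeds[hist])
        b = hist * nbatch // n
        cnt = 0
        esc = 0.0
        nsteps = 0
        sp = 0
        st_px[sp] = entries[hist, 0]
        st_py[sp] = entries[hist, 1]
        st_pz[sp] = entries[hist, 2]
        st_ux[sp] = dirs[hist, 0]
        st_uy[sp] = dirs[hist, 1]
        st_uz[sp] = dirs[hist, 2]
        st_e[sp] = e0
        st_t[sp] = 0.0
        sp = 1
        while sp > 0:
            sp -= 1
            px = st_px[sp]
            py = st_py[sp]
            pz = st_pz[sp]
            ux = st_ux[sp]
            uy = st_uy[sp]
            uz = st_uz[sp]
            e = st_e[sp]
            t_rl = st_t[sp]
            guard = 0
            while True:
                guard += 1
                if guard > 200000:
                    # pathological history: deposit on the spot and stop
                    i = int(math.floor((px - ox) / dx))
                    j = int(math.floor((py - oy) / dy))
                    k = int(math.floor((pz - oz) / dz))
                    if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                        v = (i * ny + j) * nz + k
                        cnt = _dep(cur, stamp, touched, cnt, hist, v, e, hsum)
                    else:
                        esc += e
                    break
                i = int(math.floor((px - ox) / dx))
                j = int(math.floor((py - oy) / dy))
                k = int(math.floor((pz - oz) / dz))
                if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                    esc += e
                    break
                if e < e_min:
                    cnt, lost = csda_deposit_k(hu, nodes, dens, msprs, acss,
                                               ox, oy, oz, dx, dy, dz,
                                               px, py, pz, ux, uy, uz, e,
                                               cur, stamp, touched, cnt, hist, hsum)
                    esc += lost
                    break

                hu0 = np.float64(hu[i, j, k])
                bnd = band_lower_node(hu0, nodes)
                node = bnd  # provisional; refined to the path-averaged mix
                a_mix = ramp_interp(hu0, nodes, acss)

                # nearest energy grid point
                ei = 0
                bestde = 1e30
                for q in range(ne):
                    dd = abs(evals[q] - e)
                    if dd < bestde:
                        bestde = dd
                        ei = q
                eg = evals[ei]

                # slab availability: recorded for both bracketing nodes
                # (the sampling node is drawn after the slab is chosen) and
                # within 0.6x residual range
                rmax = 0.6 * csda_range_k(a_mix, e)
                smallest_idx = -1
                for q in range(nt):
                    ok = avail[bnd, ei, q] != 0 and avail[bnd + 1, ei, q] != 0
                    if ok and smallest_idx < 0:
                        smallest_idx = q
                    avail_j[q] = 1 if (ok and tvals[q] <= rmax) else 0
                if smallest_idx < 0:
                    # no database coverage at all: fall back to CSDA
                    cnt, lost = csda_deposit_k(hu, nodes, dens, msprs, acss,
                                               ox, oy, oz, dx, dy, dz,
                                               px, py, pz, ux, uy, uz, e,
                                               cur, stamp, touched, cnt, hist, hsum)
                    esc += lost
                    break

                if mode_non_adaptive:
                    d = distance_to_interface_k(hu, nodes, ox, oy, oz, dx, dy, dz,
                                                px, py, pz, ux, uy, uz, t_max, True)
                    if d <= 0.0:
                        d = 1e-6
                    # largest available slab not exceeding the HU-change distance
                    sj = -1
                    for q in range(nt):
                        if avail_j[q] and tvals[q] <= d + 1e-9:
                            sj = q
                    if sj < 0:
                        for q in range(nt):
                            if avail_j[q]:
                                sj = q
                                break
                        if sj < 0:
                            sj = smallest_idx
                else:
                    d = distance_to_interface_k(hu, nodes, ox, oy, oz, dx, dy, dz,
                                                px, py, pz, ux, uy, uz, t_max, False)
                    if d <= 0.0:
                        d = 1e-6
                    lat = lateral_radius
                    if lateral_enabled:
                        # largest candidate step length for the lateral scan
                        cand = d
                        for q in range(nt - 1, -1, -1):
                            if avail_j[q]:
                                if tvals[q] < cand:
                                    cand = tvals[q]
                                break
                        lat = lateral_interface_distance_k(
                            hu, nodes, ox, oy, oz, dx, dy, dz,
                            px, py, pz, ux, uy, uz, cand, lateral_radius)
                    sj = _choose_slab_idx(avail_j, tvals, d, lat, lateral_thr,
                                          smallest_idx)
                slab = tvals[sj]

                # represent the slab by the path-averaged material along the
                # intended step (HU varies inside a mixed band); the straight
                # ray over the chosen slab cannot cross an interface because
                # the raytraced distance d bounds it
                hu_eff, rho_eff, rsc_eff, a_eff = segment_mean_props(
                    hu, nodes, dens, msprs, acss, scats,
                    ox, oy, oz, dx, dy, dz,
                    px, py, pz, ux, uy, uz, slab)
                bnd = band_lower_node(hu_eff, nodes)
                hlo = nodes[bnd]
                hhi = nodes[bnd + 1]
                hcl = min(max(hu_eff, hlo), hhi)
                w = (hcl - hlo) / (hhi - hlo)
                node = bnd + 1 if np.random.random() < w else bnd
                rho_mix = rho_eff
                a_mix = a_eff
                if avail[node, ei, sj] == 0:
                    # no record for this node at the chosen slab: try the
                    # other bracketing node, else drop to the smallest slab
                    other = bnd if node != bnd else bnd + 1
                    if avail[other, ei, sj] != 0:
                        node = other
                    else:
                        sj = 0
                        slab = tvals[0]
                rho_node = dens[node]
                a_node = acss[node]

                # ---- sample the macro step from the database ----
                de = _sample_cdf(de_cdf[node, ei, sj], de_lo[node, ei, sj],
                                 de_hi[node, ei, sj])
                # first-order correction of the energy loss to the actual
                # (mixed material, energy): closed-form CSDA loss ratio
                num = e - residual_energy_k(a_mix, csda_range_k(a_mix, e) - slab)
                den = eg - residual_energy_k(a_node, csda_range_k(a_node, eg) - slab)
                # mean-shift rather than scale: preserves the (energy-
                # independent) straggling width of the record
                if den > 1e-9:
                    de += de_mean[node, ei, sj] * (num / den - 1.0)
                if de < 0.0:
                    de = 0.0
                elif de > e:
                    de = e

                th, dsp = _sample_joint(ex_cdf[node, ei, sj],
                                        n_angle, n_disp,
                                        th_hi[node, ei, sj],
                                        disp_hi[node, ei, sj])
                # pv correction evaluated at mid-slab residual energies: for
                # low-energy records a large fraction of the energy is lost
                # inside the slab, so the start-of-slab pv ratio would
                # misrepresent the internally accumulated scattering
                em_node = residual_energy_k(
                    a_node, csda_range_k(a_node, eg) - 0.5 * slab)
                em_mix = residual_energy_k(
                    a_mix, csda_range_k(a_mix, e) - 0.5 * slab)
                if em_node < 0.5:
                    em_node = 0.5
                if em_mix < 0.5:
                    em_mix = 0.5
                rsc_node = rho_node * scats[node]
                kk = math.sqrt(rsc_eff / rsc_node) * \
                    (momentum_velocity(em_node) / momentum_velocity(em_mix))
                # telescoping correction: chained slabs sampled from zero
                # cumulative path under-accumulate the Highland variance;
                # rescale to the proton's cumulative radiation-length path
                t_inc = slab * rsc_eff / x0w
                f_slab = _highland_var_t(e, t_inc, hc, x0w)
                if f_slab > 0.0:
                    f_tel = _highland_var_t(e, t_rl + t_inc, hc, x0w) - \
                        _highland_var_t(e, t_rl, hc, x0w)
                    if f_tel > 0.0:
                        kk *= math.sqrt(f_tel / f_slab)
                # second-order path-length correction: the slab record's
                # internal wiggle was accumulated from a zero scattering
                # history, while the proton's cumulative Highland variance
                # grows faster deeper in the track; add the stopping-power
                # cost of the telescoped excess path inside this slab
                aa = hc / momentum_velocity(em_mix)
                aa = aa * aa
                extra = aa * (x0w / rsc_eff) * (
                    _highland_g_int(t_rl + t_inc) - _highland_g_int(t_rl)
                    - _highland_g(t_rl) * t_inc - _highland_g_int(t_inc))
                if extra > 0.0:
                    de += extra * stopping_power_k(a_mix, em_mix)
                    if de > e:
                        de = e
                th *= kk
                if th > 1.4:
                    th = 1.4
                dsp *= kk
                if dsp > 0.9 * slab:
                    dsp = 0.9 * slab

                # hard-interaction probabilities, rescaled to the actual
                # material/energy by the analytic cross-section ratio
                pe = p_el[node, ei, sj]
                pi = p_inel[node, ei, sj]
                snode = sigma_inelastic(eg, rho_node, xs_inel, nuc_thr) + \
                    sigma_elastic(eg, rho_node, xs_el, nuc_thr)
                smix = sigma_inelastic(e, rho_mix, xs_inel, nuc_thr) + \
                    sigma_elastic(e, rho_mix, xs_el, nuc_thr)
                if snode > 1e-12:
                    ratio = smix / snode
                    pe *= ratio
                    pi *= ratio
                if pe + pi > 0.9:
                    sc = 0.9 / (pe + pi)
                    pe *= sc
                    pi *= sc
                uproc = np.random.random()
                proc = 0
                frac = 1.0
                if uproc < pi:
                    proc = 2
                elif uproc < pi + pe:
                    proc = 1
                if proc != 0:
                    depth = _sample_cdf(dep_cdf[node, ei, sj], 0.0, slab)
                    frac = depth / slab
                    if frac <= 1e-6:
                        frac = 1e-6
                    elif frac > 1.0:
                        frac = 1.0

                # ---- exit position / direction ----
                phi = 2.0 * math.pi * np.random.random()
                if abs(uz) < 0.9:
                    nn = math.sqrt(ux * ux + uy * uy)
                    e1x, e1y, e1z = uy / nn, -ux / nn, 0.0
                else:
                    nn = math.sqrt(uy * uy + uz * uz)
                    e1x, e1y, e1z = 0.0, uz / nn, -uy / nn
                e2x = uy * e1z - uz * e1y
                e2y = uz * e1x - ux * e1z
                e2z = ux * e1y - uy * e1x
                lx = math.cos(phi) * e1x + math.sin(phi) * e2x
                ly = math.cos(phi) * e1y + math.sin(phi) * e2y
                lz = math.cos(phi) * e1z + math.sin(phi) * e2z
                xox = px + slab * ux + dsp * lx
                xoy = py + slab * uy + dsp * ly
                xoz = pz + slab * uz + dsp * lz
                dphi = azimuth_sigma * np.random.normal(0.0, 1.0)
                oux, ouy, ouz = rotate_direction(ux, uy, uz, th, phi + dphi)

                # ---- hinge track ----
                hx = px + hinge_fraction * slab * ux
                hy = py + hinge_fraction * slab * uy
                hz = pz + hinge_fraction * slab * uz
                l1 = hinge_fraction * slab
                g2x = xox - hx
                g2y = xoy - hy
                g2z = xoz - hz
                l2 = math.sqrt(g2x * g2x + g2y * g2y + g2z * g2z)
                ltot = l1 + l2
                target = frac * ltot if proc != 0 else ltot

                nseg = 0
                # leg 1: along u_init
                nseg, c1, stat, sx, sy, sz = walk_segment(
                    hu, nodes, ox, oy, oz, dx, dy, dz,
                    px, py, pz, ux, uy, uz, l1,
                    target, hu0, 1 if not mode_non_adaptive else 2,
                    seg_vox, seg_len, seg_t0, nseg, 0.0)
                consumed = c1
                legux, leguy, leguz = ux, uy, uz
                if stat == WALK_FULL and l2 > 1e-12:
                    iv2 = 1.0 / l2
                    legux, leguy, leguz = g2x * iv2, g2y * iv2, g2z * iv2
                    nseg, c2, stat, sx, sy, sz = walk_segment(
                        hu, nodes, ox, oy, oz, dx, dy, dz,
                        hx, hy, hz, legux, leguy, leguz, l2,
                        target, hu0, 1 if not mode_non_adaptive else 2,
                        seg_vox, seg_len, seg_t0, nseg, consumed)
                    consumed += c2

                # rho*mSPR per traversed segment
                for s in range(nseg):
                    vv = seg_vox[s]
                    kk3 = vv % nz
                    jj3 = (vv // nz) % ny
                    ii3 = vv // (nz * ny)
                    hseg = np.float64(hu[ii3, jj3, kk3])
                    seg_rm[s] = ramp_interp(hseg, nodes, dens) * \
                        ramp_interp(hseg, nodes, msprs)

                if ltot > 1e-12 and consumed < ltot - 1e-12:
                    if use_closed_partial:
                        # closed-form partial loss over the traversed slab
                        # fraction (the linear fraction overcharges the
                        # proximal part as the stopping power rises)
                        fx = consumed / ltot
                        r_eff = csda_range_k(a_mix, e)
                        npart = e - residual_energy_k(a_mix, r_eff - slab * fx)
                        nfull = e - residual_energy_k(a_mix, r_eff - slab)
                        de_dep = de * (npart / nfull) if nfull > 1e-12 \
                            else de * fx
                    else:
                        de_dep = de * (consumed / ltot)
                else:
                    de_dep = de
                if de_dep > e:
                    de_dep = e
                cnt = spa_deposit_k(seg_vox, seg_len, seg_rm, nseg, de_dep, e,
                                    scratch, cur, stamp, touched, cnt, hist, hsum)
                e -= de_dep
                nsteps += 1
                t_rl += t_inc * (consumed / ltot if ltot > 1e-12 else 1.0)

                if stat == WALK_EXIT:
                    esc += e
                    break
                if stat == WALK_BREAK:
                    # material interface crossed: resume toward x_out
                    nx2 = xox - sx
                    ny2 = xoy - sy
                    nz2 = xoz - sz
                    nn2 = math.sqrt(nx2 * nx2 + ny2 * ny2 + nz2 * nz2)
                    if nn2 > 1e-9:
                        ux, uy, uz = nx2 / nn2, ny2 / nn2, nz2 / nn2
                    else:
                        ux, uy, uz = oux, ouy, ouz
                    # nudge into the next voxel along the travel direction
                    px = sx + 1e-6 * legux
                    py = sy + 1e-6 * leguy
                    pz = sz + 1e-6 * leguz
                    continue
                if proc != 0:
                    # direction at the process point: path-fraction blend
                    f = frac
                    bx = (1.0 - f) * ux + f * oux
                    by = (1.0 - f) * uy + f * ouy
                    bz = (1.0 - f) * uz + f * ouz
                    bn = math.sqrt(bx * bx + by * by + bz * bz)
                    if bn > 1e-9:
                        bx, by, bz = bx / bn, by / bn, bz / bn
                    else:
                        bx, by, bz = oux, ouy, ouz
                    pi3 = int(math.floor((sx - ox) / dx))
                    pj3 = int(math.floor((sy - oy) / dy))
                    pk3 = int(math.floor((sz - oz) / dz))
                    inside = 0 <= pi3 < nx and 0 <= pj3 < ny and 0 <= pk3 < nz
                    if proc == 1:
                        eth, ephi, rec = sample_elastic(e, elastic_angle_mev,
                                                        recoil_fraction)
                        if inside:
                            pv3 = (pi3 * ny + pj3) * nz + pk3
                            cnt = _dep(cur, stamp, touched, cnt, hist, pv3, rec, hsum)
                        else:
                            esc += rec
                        if e - rec > 0.0:
                            if sp < smax:
                                cx, cy, cz = rotate_direction(bx, by, bz, eth, ephi)
                                st_px[sp] = sx
                                st_py[sp] = sy
                                st_pz[sp] = sz
                                st_ux[sp] = cx
                                st_uy[sp] = cy
                                st_uz[sp] = cz
                                st_e[sp] = e - rec
                                st_t[sp] = t_rl
                                sp += 1
                            elif inside:
                                pv3 = (pi3 * ny + pj3) * nz + pk3
                                cnt = _dep(cur, stamp, touched, cnt, hist, pv3,
                                           e - rec, hsum)
                            else:
                                esc += e - rec
                    else:
                        ep, sth, sphi, en, elocal = sample_inelastic_split(
                            e, neutron_fraction, sec_angle_sigma)
                        if inside:
                            pv3 = (pi3 * ny + pj3) * nz + pk3
                            cnt = _dep(cur, stamp, touched, cnt, hist, pv3, elocal, hsum)
                        else:
                            esc += elocal
                        esc += en
                        if ep > 0.0:
                            if sp < smax:
                                cx, cy, cz = rotate_direction(bx, by, bz, sth, sphi)
                                st_px[sp] = sx
                                st_py[sp] = sy
                                st_pz[sp] = sz
                                st_ux[sp] = cx
                                st_uy[sp] = cy
                                st_uz[sp] = cz
                                st_e[sp] = ep
                                st_t[sp] = 0.0
                                sp += 1
                            elif inside:
                                pv3 = (pi3 * ny + pj3) * nz + pk3
                                cnt = _dep(cur, stamp, touched, cnt, hist, pv3,
                                           ep, hsum)
                            else:
                                esc += ep
                    break
                # ordinary macro step: move on
                px, py, pz = xox, xoy, xoz
                ux, uy, uz = oux, ouy, ouz
        dep_out[hist] = _flush(cur, touched, cnt, hsum, hsumsq, batch, b)
        esc_out[hist] = esc
        steps_out[hist] = nsteps
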