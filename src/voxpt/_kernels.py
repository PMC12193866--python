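"""Compiled numerical kernels.

Everything that runs per sample point or per path lives here as numba
``njit`` functions over flat arrays: volume interpolation, transfer-function
manager evaluation, octree update and multi-level traversal, ratio-tracking
transmittance, collision sampling and the full path-tracing estimator.

The Python object layer (:mod:`voxpt.tf`, :mod:`voxpt.octree`,
:mod:`voxpt.render`) flattens scenes to the array layout pinned in
:mod:`voxpt._layout` and calls in here; tests cross-check these kernels
against independent pure-Python oracles.

Randomness is counter-based: every path derives a splitmix64 stream from
(seed, pixel, sample), so renders are bit-reproducible regardless of
execution order.
"""

import math

import numpy as np
from numba import njit

from ._layout import (C_A, C_G, C_KIND, C_LE, C_METAL, C_OP, C_ROUGH, C_S,
                      C_SURF, NC, NOUT, O_A, O_G, O_GRAD, O_KIND, O_LE,
                      O_METAL, O_OP, O_PFS, O_ROUGH, O_S, O_SFS, O_SIGA,
                      O_SIGS, O_SIGT, O_SVS, O_W)

U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0
_MAX_SEG = 4096


# ---------------------------------------------------------------------------
# counter-based RNG (splitmix64)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mix64(z):
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True)
def rng_init(seed, a, b):
    s = _mix64(U64(seed) + U64(0x9E3779B97F4A7C15))
    s = _mix64(s ^ _mix64(U64(a) + U64(0xBF58476D1CE4E5B9)))
    return _mix64(s ^ _mix64(U64(b) + U64(0x94D049BB133111EB)))


@njit(cache=True)
def rng_next(state):
    state = state + U64(0x9E3779B97F4A7C15)
    z = _mix64(state)
    return state, float(z >> U64(11)) * _INV53


# ---------------------------------------------------------------------------
# volume sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_vol(arr, meta, px, py, pz):
    """Sample one proxy volume at a world point (0 outside support)."""
    nx = int(meta[2]); ny = int(meta[3]); nz = int(meta[4])
    rx = (px - meta[8]) / meta[5]
    ry = (py - meta[9]) / meta[6]
    rz = (pz - meta[10]) / meta[7]
    if (rx < -0.5 or rx > nx - 0.5 or ry < -0.5 or ry > ny - 0.5
            or rz < -0.5 or rz > nz - 0.5):
        return 0.0
    if meta[1] > 0.5:  # discrete: nearest voxel centre
        ix = int(math.floor(rx + 0.5))
        iy = int(math.floor(ry + 0.5))
        iz = int(math.floor(rz + 0.5))
        if ix < 0: ix = 0
        if iy < 0: iy = 0
        if iz < 0: iz = 0
        if ix > nx - 1: ix = nx - 1
        if iy > ny - 1: iy = ny - 1
        if iz > nz - 1: iz = nz - 1
        return float(arr[ix, iy, iz])
    i0 = int(math.floor(rx))
    j0 = int(math.floor(ry))
    k0 = int(math.floor(rz))
    if i0 < 0: i0 = 0
    if j0 < 0: j0 = 0
    if k0 < 0: k0 = 0
    if i0 > nx - 1: i0 = nx - 1
    if j0 > ny - 1: j0 = ny - 1
    if k0 > nz - 1: k0 = nz - 1
    fx = rx - i0
    fy = ry - j0
    fz = rz - k0
    if fx < 0.0: fx = 0.0
    if fy < 0.0: fy = 0.0
    if fz < 0.0: fz = 0.0
    if fx > 1.0: fx = 1.0
    if fy > 1.0: fy = 1.0
    if fz > 1.0: fz = 1.0
    i1 = min(i0 + 1, nx - 1)
    j1 = min(j0 + 1, ny - 1)
    k1 = min(k0 + 1, nz - 1)
    c00 = arr[i0, j0, k0] * (1 - fx) + arr[i1, j0, k0] * fx
    c10 = arr[i0, j1, k0] * (1 - fx) + arr[i1, j1, k0] * fx
    c01 = arr[i0, j0, k1] * (1 - fx) + arr[i1, j0, k1] * fx
    c11 = arr[i0, j1, k1] * (1 - fx) + arr[i1, j1, k1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return float(c0 * (1 - fz) + c1 * fz)


@njit(cache=True)
def _proxy_sample(slot, v0, v1, v2, v3, vmeta, px, py, pz):
    if slot == 0:
        return _sample_vol(v0, vmeta[0], px, py, pz)
    elif slot == 1:
        return _sample_vol(v1, vmeta[1], px, py, pz)
    elif slot == 2:
        return _sample_vol(v2, vmeta[2], px, py, pz)
    return _sample_vol(v3, vmeta[3], px, py, pz)


@njit(cache=True)
def _grad_primary(v0, vmeta, px, py, pz):
    """Central-difference gradient of the primary volume (world units)."""
    g = np.empty(3)
    p = np.empty(3)
    p[0] = px; p[1] = py; p[2] = pz
    for a in range(3):
        h = vmeta[0, 5 + a]
        lo = vmeta[0, 8 + a] - 0.5 * h + 1e-9
        hi = vmeta[0, 8 + a] + (vmeta[0, 2 + a] - 0.5) * h - 1e-9
        up = p[a] + h
        dn = p[a] - h
        if up > hi: up = hi
        if dn < lo: dn = lo
        denom = up - dn
        if denom <= 0.0:
            g[a] = 0.0
            continue
        sav = p[a]
        p[a] = up
        fp = _sample_vol(v0, vmeta[0], p[0], p[1], p[2])
        p[a] = dn
        fm = _sample_vol(v0, vmeta[0], p[0], p[1], p[2])
        p[a] = sav
        g[a] = (fp - fm) / denom
    return g[0], g[1], g[2]


# ---------------------------------------------------------------------------
# transfer-function manager evaluation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eval_binding(b, v, bform, bxs_off, bcf_off, xs, coef, rb):
    """Evaluate one binding at proxy value v; writes a coefficient row."""
    form = bform[b]
    x0 = bxs_off[b]
    x1 = bxs_off[b + 1]
    c0 = bcf_off[b]
    n = x1 - x0
    if form == 0:  # CCTF: clamp to control range, lerp component-wise
        if v <= xs[x0]:
            for c in range(NC):
                rb[c] = coef[c0, c]
            return
        if v >= xs[x1 - 1]:
            for c in range(NC):
                rb[c] = coef[c0 + n - 1, c]
            return
        j = x0 + 1
        while xs[j] < v:
            j += 1
        t = (v - xs[j - 1]) / (xs[j] - xs[j - 1])
        r0 = c0 + (j - 1 - x0)
        for c in range(NC):
            rb[c] = (1.0 - t) * coef[r0, c] + t * coef[r0 + 1, c]
        rb[C_KIND] = coef[r0, C_KIND]
        rb[C_SURF] = coef[r0, C_SURF]
        return
    if form == 1 or form == 3:  # piecewise constant, [b_i, b_{i+1})
        idx = 0
        for j in range(n):
            if v >= xs[x0 + j]:
                idx = j + 1
            else:
                break
        for c in range(NC):
            rb[c] = coef[c0 + idx, c]
        return
    # discrete point forms: exact label match, else unclassified (opacity 0)
    for j in range(n):
        if abs(xs[x0 + j] - v) < 1e-6:
            for c in range(NC):
                rb[c] = coef[c0 + j, c]
            return
    for c in range(NC):
        rb[c] = 0.0
    rb[C_SURF] = -1.0


@njit(cache=True)
def eval_props(px, py, pz, v0, v1, v2, v3, vmeta, bproxy, bform, bxs_off,
               bcf_off, xs, coef, tfp, out):
    """Full manager evaluation at a world point -> optical property row."""
    mode = int(tfp[0])
    sref = tfp[1]
    gref = tfp[2]
    gam = tfp[3]
    chan = int(tfp[4])
    B = bform.shape[0]
    acc = np.zeros(NC)
    rb = np.empty(NC)
    if mode == 0:  # multiply
        acc[C_OP] = 1.0
        for c in range(3):
            acc[C_A + c] = 1.0
            acc[C_S + c] = 1.0
            acc[C_LE + c] = 1.0
        acc[C_SURF] = -1.0
        wsum = 0.0
        racc = 0.0
        macc = 0.0
        gacc = 0.0
        kind_set = False
        first_kind = 0.0
        first_surf = -1.0
        for b in range(B):
            v = _proxy_sample(bproxy[b], v0, v1, v2, v3, vmeta, px, py, pz)
            _eval_binding(b, v, bform, bxs_off, bcf_off, xs, coef, rb)
            acc[C_OP] *= rb[C_OP]
            for c in range(3):
                acc[C_A + c] *= rb[C_A + c]
                acc[C_S + c] *= rb[C_S + c]
                acc[C_LE + c] *= rb[C_LE + c]
            wgt = rb[C_OP]
            wsum += wgt
            racc += wgt * rb[C_ROUGH]
            macc += wgt * rb[C_METAL]
            gacc += wgt * rb[C_G]
            if b == 0:
                first_kind = rb[C_KIND]
                first_surf = rb[C_SURF]
            if not kind_set and bform[b] >= 3:
                acc[C_KIND] = rb[C_KIND]
                acc[C_SURF] = rb[C_SURF]
                kind_set = True
        if not kind_set:
            acc[C_KIND] = first_kind
            acc[C_SURF] = first_surf
        if wsum > 0.0:
            acc[C_ROUGH] = racc / wsum
            acc[C_METAL] = macc / wsum
            acc[C_G] = gacc / wsum
        else:
            acc[C_ROUGH] = 0.3
    else:  # priority: first (highest-priority) binding with opacity > 0
        hit = False
        for b in range(B):
            v = _proxy_sample(bproxy[b], v0, v1, v2, v3, vmeta, px, py, pz)
            _eval_binding(b, v, bform, bxs_off, bcf_off, xs, coef, rb)
            if rb[C_OP] > 0.0:
                for c in range(NC):
                    acc[c] = rb[c]
                hit = True
                break
        if not hit:
            acc[C_SURF] = -1.0

    for c in range(NOUT):
        out[c] = 0.0
    out[O_KIND] = acc[C_KIND]
    op = acc[C_OP]
    out[O_OP] = op
    if op <= 0.0:
        return
    sigt = op * sref
    gx, gy, gz = _grad_primary(v0, vmeta, px, py, pz)
    gmag = math.sqrt(gx * gx + gy * gy + gz * gz)
    surf = acc[C_SURF]
    if surf >= 0.0:
        pfs = surf
    elif gref > 0.0:
        ratio = gmag / gref
        pfs = ratio ** gam
        if pfs > 1.0:
            pfs = 1.0
    else:
        pfs = 0.0
    if gmag < 1e-12:
        pfs = 0.0  # no normal available: never a surface event
    amax = 0.0
    smax = 0.0
    for c in range(3):
        a = acc[C_A + c]
        if a < 0.0: a = 0.0
        if a > 1.0: a = 1.0
        s = acc[C_S + c]
        if s < 0.0: s = 0.0
        if s > 1.0: s = 1.0
        out[O_A + c] = a
        out[O_S + c] = s
        out[O_LE + c] = acc[C_LE + c]
        if a > amax: amax = a
        if s > smax: smax = s
    if pfs <= 0.0:
        amax = 0.0
    if pfs >= 1.0:
        smax = 0.0
    w = amax if amax > smax else smax
    out[O_SIGT] = sigt
    out[O_PFS] = pfs
    out[O_ROUGH] = acc[C_ROUGH]
    out[O_METAL] = acc[C_METAL]
    out[O_G] = acc[C_G]
    out[O_GRAD + 0] = gx
    out[O_GRAD + 1] = gy
    out[O_GRAD + 2] = gz
    out[O_W] = w
    for c in range(3):
        if chan == 0:  # single-channel sigma_t; colour lives in albedo
            svs = (1.0 - pfs) * w * sigt
            sfs = pfs * w * sigt
        else:  # per-channel coefficients, sigma_t stays channel-uniform
            svs = (1.0 - pfs) * out[O_S + c] * sigt
            sfs = pfs * out[O_A + c] * sigt
        out[O_SVS + c] = svs
        out[O_SFS + c] = sfs
        out[O_SIGS + c] = svs + sfs
        out[O_SIGA + c] = sigt - svs - sfs


@njit(cache=True)
def eval_props_many(points, v0, v1, v2, v3, vmeta, bproxy, bform, bxs_off,
                    bcf_off, xs, coef, tfp, out):
    for i in range(points.shape[0]):
        eval_props(points[i, 0], points[i, 1], points[i, 2], v0, v1, v2, v3,
                   vmeta, bproxy, bform, bxs_off, bcf_off, xs, coef, tfp,
                   out[i])


@njit(cache=True)
def sigma_grid(v0, v1, v2, v3, vmeta, bproxy, bform, bxs_off, bcf_off, xs,
               coef, tfp, sig):
    """Post-classification extinction at every primary voxel centre."""
    nx, ny, nz = sig.shape
    row = np.empty(NOUT)
    for i in range(nx):
        px = vmeta[0, 8] + i * vmeta[0, 5]
        for j in range(ny):
            py = vmeta[0, 9] + j * vmeta[0, 6]
            for k in range(nz):
                pz = vmeta[0, 10] + k * vmeta[0, 7]
                eval_props(px, py, pz, v0, v1, v2, v3, vmeta, bproxy, bform,
                           bxs_off, bcf_off, xs, coef, tfp, row)
                sig[i, j, k] = row[O_SIGT]


# ---------------------------------------------------------------------------
# octree update and traversal
# ---------------------------------------------------------------------------

@njit(cache=True)
def leaf_range_reduce(grid, lo, hi, out_min, out_max):
    """Per-leaf min/max of a voxel grid over inclusive index boxes."""
    for q in range(lo.shape[0]):
        mn = grid[lo[q, 0], lo[q, 1], lo[q, 2]]
        mx = mn
        for i in range(lo[q, 0], hi[q, 0] + 1):
            for j in range(lo[q, 1], hi[q, 1] + 1):
                for k in range(lo[q, 2], hi[q, 2] + 1):
                    v = grid[i, j, k]
                    if v > mx:
                        mx = v
                    if v < mn:
                        mn = v
        out_min[q] = mn
        out_max[q] = mx


@njit(cache=True)
def octree_fill_up(leaf_vals, max_ext, level_off, leaf_level):
    """Assign leaf majorants and propagate maxima bottom-up."""
    off = level_off[leaf_level]
    for q in range(leaf_vals.shape[0]):
        max_ext[off + q] = leaf_vals[q]
    for lev in range(leaf_level - 1, -1, -1):
        n = 1 << lev
        nc = n << 1
        po = level_off[lev]
        co = level_off[lev + 1]
        for cx in range(n):
            for cy in range(n):
                for cz in range(n):
                    m = 0.0
                    for dx in range(2):
                        for dy in range(2):
                            for dz in range(2):
                                ci = co + (((cx * 2 + dx) * nc
                                            + (cy * 2 + dy)) * nc
                                           + (cz * 2 + dz))
                                v = max_ext[ci]
                                if v > m:
                                    m = v
                    max_ext[po + (cx * n + cy) * n + cz] = m


@njit(cache=True)
def _ray_box(ox, oy, oz, dx, dy, dz, bx0, by0, bz0, bx1, by1, bz1):
    t0 = -1e30
    t1 = 1e30
    for a in range(3):
        if a == 0:
            o = ox; d = dx; lo = bx0; hi = bx1
        elif a == 1:
            o = oy; d = dy; lo = by0; hi = by1
        else:
            o = oz; d = dz; lo = bz0; hi = bz1
        if abs(d) < 1e-14:
            if o < lo or o > hi:
                return False, 0.0, 0.0
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return False, 0.0, 0.0
    return True, t0, t1


@njit(cache=True)
def _box_exit(ox, oy, oz, dx, dy, dz, cx, cy, cz, lev, obmin, obsize):
    n = 1 << lev
    te = 1e30
    for a in range(3):
        edge = obsize[a] / n
        if a == 0:
            c = cx; o = ox; d = dx
        elif a == 1:
            c = cy; o = oy; d = dy
        else:
            c = cz; o = oz; d = dz
        lo = obmin[a] + c * edge
        hi = lo + edge
        if d > 1e-14:
            t = (hi - o) / d
        elif d < -1e-14:
            t = (lo - o) / d
        else:
            continue
        if t < te:
            te = t
    return te


@njit(cache=True)
def traverse(ox, oy, oz, dx, dy, dz, tmin, tmax, max_ext, level_off,
             leaf_level, obmin, obsize, hd_abs, hu_abs, use_global,
             seg_t0, seg_t1, seg_maj, seg_node):
    """Walk a ray through the hierarchy; emit majorant segments.

    Implements the level rules: invalid nodes are climbed and skipped whole;
    a node max below hd climbs (unless the parent exceeds hu); above hu
    descends toward the leaves; in between (or at root/leaf) the node is
    emitted for volumetric sampling.  Returns the segment count.
    """
    nseg = 0
    if max_ext[0] <= 0.0:
        return 0
    if use_global != 0:
        seg_t0[0] = tmin
        seg_t1[0] = tmax
        seg_maj[0] = max_ext[0]
        seg_node[0] = 0
        return 1
    min_edge_root = obsize[0]
    for a in range(3):
        if obsize[a] < min_edge_root:
            min_edge_root = obsize[a]
    t = tmin
    lev = leaf_level
    it = 0
    while t < tmax - 1e-12:
        it += 1
        if it > 10000000:
            raise RuntimeError("octree traversal failed to make progress")
        n = 1 << lev
        probe = t + 1e-7 * min_edge_root / n
        px = ox + dx * probe
        py = oy + dy * probe
        pz = oz + dz * probe
        cx = int(math.floor((px - obmin[0]) / (obsize[0] / n)))
        cy = int(math.floor((py - obmin[1]) / (obsize[1] / n)))
        cz = int(math.floor((pz - obmin[2]) / (obsize[2] / n)))
        if cx < 0: cx = 0
        if cy < 0: cy = 0
        if cz < 0: cz = 0
        if cx > n - 1: cx = n - 1
        if cy > n - 1: cy = n - 1
        if cz > n - 1: cz = n - 1
        idx = level_off[lev] + (cx * n + cy) * n + cz
        m = max_ext[idx]
        if m <= 0.0:
            # climb to the highest invalid ancestor whose parent is valid
            while lev > 0:
                pn = 1 << (lev - 1)
                pidx = level_off[lev - 1] + (((cx >> 1) * pn + (cy >> 1)) * pn
                                             + (cz >> 1))
                if max_ext[pidx] > 0.0:
                    break
                lev -= 1
                cx >>= 1
                cy >>= 1
                cz >>= 1
            te = _box_exit(ox, oy, oz, dx, dy, dz, cx, cy, cz, lev,
                           obmin, obsize)
            t = te + 1e-5 * min_edge_root / (1 << lev)
            continue
        if m > hu_abs and lev < leaf_level:
            lev += 1
            continue
        if m < hd_abs and lev > 0:
            pn = 1 << (lev - 1)
            pidx = level_off[lev - 1] + (((cx >> 1) * pn + (cy >> 1)) * pn
                                         + (cz >> 1))
            if max_ext[pidx] <= hu_abs:
                lev -= 1
                continue
        te = _box_exit(ox, oy, oz, dx, dy, dz, cx, cy, cz, lev, obmin, obsize)
        tec = te if te < tmax else tmax
        if tec > t + 1e-12:
            if nseg >= _MAX_SEG:
                raise RuntimeError("traversal segment buffer overflow")
            seg_t0[nseg] = t
            seg_t1[nseg] = tec
            seg_maj[nseg] = m
            seg_node[nseg] = idx
            nseg += 1
        t = te + 1e-5 * min_edge_root / (1 << lev)
    return nseg


# ---------------------------------------------------------------------------
# phase function / PSF helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hg_eval(g, mu):
    g2 = g * g
    denom = 1.0 + g2 - 2.0 * g * mu
    if denom < 1e-12:
        denom = 1e-12
    return (1.0 - g2) / (4.0 * math.pi * denom * math.sqrt(denom))


@njit(cache=True)
def _onb(wx, wy, wz):
    if abs(wx) < 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 1.0, 0.0
    tx = wy * az - wz * ay
    ty = wz * ax - wx * az
    tz = wx * ay - wy * ax
    inv = 1.0 / math.sqrt(tx * tx + ty * ty + tz * tz)
    tx *= inv; ty *= inv; tz *= inv
    ux = wy * tz - wz * ty
    uy = wz * tx - wx * tz
    uz = wx * ty - wy * tx
    return tx, ty, tz, ux, uy, uz


@njit(cache=True)
def _hg_sample(g, wx, wy, wz, state):
    state, u1 = rng_next(state)
    state, u2 = rng_next(state)
    if abs(g) < 1e-6:
        mu = 1.0 - 2.0 * u1
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        mu = (1.0 + g * g - s * s) / (2.0 * g)
    if mu < -1.0: mu = -1.0
    if mu > 1.0: mu = 1.0
    st = math.sqrt(max(0.0, 1.0 - mu * mu))
    phi = 2.0 * math.pi * u2
    tx, ty, tz, ux, uy, uz = _onb(wx, wy, wz)
    ca = math.cos(phi)
    sa = math.sin(phi)
    ox = mu * wx + st * (ca * tx + sa * ux)
    oy = mu * wy + st * (ca * ty + sa * uy)
    oz = mu * wz + st * (ca * tz + sa * uz)
    inv = 1.0 / math.sqrt(ox * ox + oy * oy + oz * oz)
    return state, ox * inv, oy * inv, oz * inv


@njit(cache=True)
def _cosine_sample(nx, ny, nz, state):
    state, u1 = rng_next(state)
    state, u2 = rng_next(state)
    ct = math.sqrt(u1)
    st = math.sqrt(max(0.0, 1.0 - u1))
    phi = 2.0 * math.pi * u2
    tx, ty, tz, ux, uy, uz = _onb(nx, ny, nz)
    ca = math.cos(phi)
    sa = math.sin(phi)
    ox = ct * nx + st * (ca * tx + sa * ux)
    oy = ct * ny + st * (ca * ty + sa * uy)
    oz = ct * nz + st * (ca * tz + sa * uz)
    return state, ox, oy, oz


@njit(cache=True)
def _lobe_exponent(rough):
    r = rough
    if r < 1e-3:
        r = 1e-3
    e = 2.0 / (r * r) - 2.0
    if e < 1.0:
        e = 1.0
    return e


@njit(cache=True)
def _psf_eval(kind, rough, nx, ny, nz, ix, iy, iz, wx, wy, wz):
    """Scalar PSF density for normal n, incident propagation i, outgoing w."""
    cos_o = nx * wx + ny * wy + nz * wz
    if cos_o <= 0.0:
        return 0.0
    if kind == 1 or kind == 2:  # metal / dielectric: powered-cosine lobe
        e = _lobe_exponent(rough)
        dn = ix * nx + iy * ny + iz * nz
        rx = ix - 2.0 * dn * nx
        ry = iy - 2.0 * dn * ny
        rz = iz - 2.0 * dn * nz
        mu = rx * wx + ry * wy + rz * wz
        if mu <= 0.0:
            return 0.0
        return (e + 2.0) / (2.0 * math.pi) * mu ** e * cos_o
    return cos_o / math.pi  # diffuse-family BSDF


@njit(cache=True)
def _env_radiance(envmap, lrgb_r, lrgb_g, lrgb_b, dx, dy, dz):
    """Lat-long environment lookup (bilinear, +y up), scaled by lrgb."""
    h = envmap.shape[0]
    w = envmap.shape[1]
    if h == 1 and w == 1:
        return lrgb_r * envmap[0, 0, 0], lrgb_g * envmap[0, 0, 1], \
            lrgb_b * envmap[0, 0, 2]
    phi = math.atan2(dz, dx)
    ct = dy
    if ct < -1.0: ct = -1.0
    if ct > 1.0: ct = 1.0
    theta = math.acos(ct)
    u = (phi + math.pi) / (2.0 * math.pi) * w - 0.5
    v = theta / math.pi * h - 0.5
    iu0 = int(math.floor(u))
    iv0 = int(math.floor(v))
    fu = u - iu0
    fv = v - iv0
    iu1 = (iu0 + 1) % w
    iu0 = iu0 % w
    if iv0 < 0:
        iv0 = 0
        fv = 0.0
    iv1 = min(iv0 + 1, h - 1)
    if iv0 > h - 1:
        iv0 = h - 1
        iv1 = h - 1
        fv = 0.0
    r = ((envmap[iv0, iu0, 0] * (1 - fu) + envmap[iv0, iu1, 0] * fu) * (1 - fv)
         + (envmap[iv1, iu0, 0] * (1 - fu) + envmap[iv1, iu1, 0] * fu) * fv)
    g = ((envmap[iv0, iu0, 1] * (1 - fu) + envmap[iv0, iu1, 1] * fu) * (1 - fv)
         + (envmap[iv1, iu0, 1] * (1 - fu) + envmap[iv1, iu1, 1] * fu) * fv)
    b = ((envmap[iv0, iu0, 2] * (1 - fu) + envmap[iv0, iu1, 2] * fu) * (1 - fv)
         + (envmap[iv1, iu0, 2] * (1 - fu) + envmap[iv1, iu1, 2] * fu) * fv)
    return lrgb_r * r, lrgb_g * g, lrgb_b * b


# ---------------------------------------------------------------------------
# transmittance (ratio tracking)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _transmit(qx, qy, qz, wx, wy, wz, dist, shadow_a, v0, v1, v2, v3, vmeta,
              bproxy, bform, bxs_off, bcf_off, xs, coef, tfp, max_ext,
              level_off, leaf_level, obmin, obsize, hd_abs, hu_abs,
              use_global, seg_t0, seg_t1, seg_maj, seg_node, row, state):
    """Ratio-tracking estimate of exp(-int a*sigma_t) along a segment."""
    hit, t0, t1 = _ray_box(qx, qy, qz, wx, wy, wz, obmin[0], obmin[1],
                           obmin[2], obmin[0] + obsize[0],
                           obmin[1] + obsize[1], obmin[2] + obsize[2])
    if not hit:
        return state, 1.0
    if t0 < 0.0:
        t0 = 0.0
    if t1 > dist:
        t1 = dist
    if t1 <= t0:
        return state, 1.0
    nseg = traverse(qx, qy, qz, wx, wy, wz, t0, t1, max_ext, level_off,
                    leaf_level, obmin, obsize, hd_abs, hu_abs, use_global,
                    seg_t0, seg_t1, seg_maj, seg_node)
    T = 1.0
    for si in range(nseg):
        M = seg_maj[si]
        t = seg_t0[si]
        while True:
            state, u = rng_next(state)
            t -= math.log(1.0 - u) / M
            if t >= seg_t1[si]:
                break
            eval_props(qx + wx * t, qy + wy * t, qz + wz * t, v0, v1, v2, v3,
                       vmeta, bproxy, bform, bxs_off, bcf_off, xs, coef, tfp,
                       row)
            sigt = row[O_SIGT]
            if sigt > M * (1.0 + 1e-6) + 1e-12:
                raise ValueError("majorant violation in transmittance "
                                 "estimate: node bound below extinction")
            f = 1.0 - shadow_a * sigt / M
            if f <= 0.0:
                return state, 0.0
            T *= f
    return state, T


@njit(cache=True)
def transmittance_batch(qx, qy, qz, wx, wy, wz, dist, shadow_a, v0, v1, v2,
                        v3, vmeta, bproxy, bform, bxs_off, bcf_off, xs, coef,
                        tfp, max_ext, level_off, leaf_level, obmin, obsize,
                        hd_abs, hu_abs, use_global, seed, out):
    seg_t0 = np.empty(_MAX_SEG)
    seg_t1 = np.empty(_MAX_SEG)
    seg_maj = np.empty(_MAX_SEG)
    seg_node = np.empty(_MAX_SEG, dtype=np.int64)
    row = np.empty(NOUT)
    for i in range(out.shape[0]):
        state = rng_init(seed, i, 0)
        state, T = _transmit(qx, qy, qz, wx, wy, wz, dist, shadow_a, v0, v1,
                             v2, v3, vmeta, bproxy, bform, bxs_off, bcf_off,
                             xs, coef, tfp, max_ext, level_off, leaf_level,
                             obmin, obsize, hd_abs, hu_abs, use_global,
                             seg_t0, seg_t1, seg_maj, seg_node, row, state)
        out[i] = T


# ---------------------------------------------------------------------------
# path tracing
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nee(qx, qy, qz, dx, dy, dz, is_surface, nx, ny, nz, kind, rough, g,
         wr, wg, wb, shadow_a, v0, v1, v2, v3, vmeta, bproxy, bform, bxs_off,
         bcf_off, xs, coef, tfp, max_ext, level_off, leaf_level, obmin,
         obsize, hd_abs, hu_abs, use_global, ltype, lrgb, lpos, envmap,
         seg_t0, seg_t1, seg_maj, seg_node, row, state):
    """Next-event estimation at a real scattering event.

    The surface/volume albedo has already been folded into the throughput
    (wr, wg, wb); only the angular density, light radiance and shadow-ray
    transmittance appear here.
    """
    ar = 0.0
    ag = 0.0
    ab = 0.0
    for li in range(ltype.shape[0]):
        lt = ltype[li]
        if lt == 2:  # point light
            lx = lpos[li, 0] - qx
            ly = lpos[li, 1] - qy
            lz = lpos[li, 2] - qz
            r2 = lx * lx + ly * ly + lz * lz
            if r2 < 1e-12:
                continue
            r = math.sqrt(r2)
            ux = lx / r
            uy = ly / r
            uz = lz / r
            if is_surface:
                fval = _psf_eval(kind, rough, nx, ny, nz, dx, dy, dz,
                                 ux, uy, uz)
            else:
                fval = _hg_eval(g, dx * ux + dy * uy + dz * uz)
            if fval <= 0.0:
                continue
            state, T = _transmit(qx, qy, qz, ux, uy, uz, r, shadow_a, v0, v1,
                                 v2, v3, vmeta, bproxy, bform, bxs_off,
                                 bcf_off, xs, coef, tfp, max_ext, level_off,
                                 leaf_level, obmin, obsize, hd_abs, hu_abs,
                                 use_global, seg_t0, seg_t1, seg_maj,
                                 seg_node, row, state)
            if T <= 0.0:
                continue
            s = fval * T / r2
            ar += wr * s * lrgb[li, 0]
            ag += wg * s * lrgb[li, 1]
            ab += wb * s * lrgb[li, 2]
        elif lt == 0:  # uniform environment: importance-sample the lobe
            fac = 1.0
            if is_surface:
                if kind == 1 or kind == 2:
                    e = _lobe_exponent(rough)
                    dn = dx * nx + dy * ny + dz * nz
                    rx = dx - 2.0 * dn * nx
                    ry = dy - 2.0 * dn * ny
                    rz = dz - 2.0 * dn * nz
                    state, u1 = rng_next(state)
                    state, u2 = rng_next(state)
                    ct = u1 ** (1.0 / (e + 1.0))
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    phi = 2.0 * math.pi * u2
                    tx, ty, tz, vx_, vy_, vz_ = _onb(rx, ry, rz)
                    ux = ct * rx + st * (math.cos(phi) * tx
                                         + math.sin(phi) * vx_)
                    uy = ct * ry + st * (math.cos(phi) * ty
                                         + math.sin(phi) * vy_)
                    uz = ct * rz + st * (math.cos(phi) * tz
                                         + math.sin(phi) * vz_)
                    cos_o = ux * nx + uy * ny + uz * nz
                    if cos_o <= 0.0:
                        continue
                    fac = (e + 2.0) / (e + 1.0) * cos_o
                else:
                    state, ux, uy, uz = _cosine_sample(nx, ny, nz, state)
                    fac = 1.0
            else:
                state, ux, uy, uz = _hg_sample(g, dx, dy, dz, state)
            state, T = _transmit(qx, qy, qz, ux, uy, uz, 1e30, shadow_a, v0,
                                 v1, v2, v3, vmeta, bproxy, bform, bxs_off,
                                 bcf_off, xs, coef, tfp, max_ext, level_off,
                                 leaf_level, obmin, obsize, hd_abs, hu_abs,
                                 use_global, seg_t0, seg_t1, seg_maj,
                                 seg_node, row, state)
            if T <= 0.0:
                continue
            ar += wr * fac * T * lrgb[li, 0]
            ag += wg * fac * T * lrgb[li, 1]
            ab += wb * fac * T * lrgb[li, 2]
        else:  # lat-long environment map: uniform-sphere sampling
            state, u1 = rng_next(state)
            state, u2 = rng_next(state)
            ct = 1.0 - 2.0 * u1
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * u2
            ux = st * math.cos(phi)
            uy = ct
            uz = st * math.sin(phi)
            if is_surface:
                fval = _psf_eval(kind, rough, nx, ny, nz, dx, dy, dz,
                                 ux, uy, uz)
            else:
                fval = _hg_eval(g, dx * ux + dy * uy + dz * uz)
            if fval <= 0.0:
                continue
            er, eg, eb = _env_radiance(envmap, lrgb[li, 0], lrgb[li, 1],
                                       lrgb[li, 2], ux, uy, uz)
            state, T = _transmit(qx, qy, qz, ux, uy, uz, 1e30, shadow_a, v0,
                                 v1, v2, v3, vmeta, bproxy, bform, bxs_off,
                                 bcf_off, xs, coef, tfp, max_ext, level_off,
                                 leaf_level, obmin, obsize, hd_abs, hu_abs,
                                 use_global, seg_t0, seg_t1, seg_maj,
                                 seg_node, row, state)
            if T <= 0.0:
                continue
            s = fval * 4.0 * math.pi * T
            ar += wr * s * er
            ag += wg * s * eg
            ab += wb * s * eb
    return state, ar, ag, ab


@njit(cache=True)
def _escape_env(dx, dy, dz, ltype, lrgb, envmap):
    """Environment radiance seen by an unscattered escaping ray."""
    r = 0.0
    g = 0.0
    b = 0.0
    for li in range(ltype.shape[0]):
        if ltype[li] == 0:
            r += lrgb[li, 0]
            g += lrgb[li, 1]
            b += lrgb[li, 2]
        elif ltype[li] == 1:
            er, eg, eb = _env_radiance(envmap, lrgb[li, 0], lrgb[li, 1],
                                       lrgb[li, 2], dx, dy, dz)
            r += er
            g += eg
            b += eb
    return r, g, b


@njit(cache=True)
def trace_path(ox, oy, oz, dx, dy, dz, v0, v1, v2, v3, vmeta, bproxy, bform,
               bxs_off, bcf_off, xs, coef, tfp, max_ext, level_off,
               leaf_level, obmin, obsize, hd_abs, hu_abs, use_global, ltype,
               lrgb, lpos, envmap, shadow_a, max_bounces, rr_start, seg_t0,
               seg_t1, seg_maj, seg_node, sseg_t0, sseg_t1, sseg_maj,
               sseg_node, row, srow, state):
    """One-sample radiance estimate for a camera ray (unit direction)."""
    Lr = 0.0
    Lg = 0.0
    Lb = 0.0
    wr = 1.0
    wg = 1.0
    wb = 1.0
    chan = int(tfp[4])
    nscat = 0
    alive = True
    for _it in range(100000):
        if not alive:
            break
        hit, t0, t1 = _ray_box(ox, oy, oz, dx, dy, dz, obmin[0], obmin[1],
                               obmin[2], obmin[0] + obsize[0],
                               obmin[1] + obsize[1], obmin[2] + obsize[2])
        if not hit or t1 <= 1e-12:
            if nscat == 0:
                er, eg, eb = _escape_env(dx, dy, dz, ltype, lrgb, envmap)
                Lr += wr * er
                Lg += wg * eg
                Lb += wb * eb
            break
        if t0 < 0.0:
            t0 = 0.0
        nseg = traverse(ox, oy, oz, dx, dy, dz, t0, t1, max_ext, level_off,
                        leaf_level, obmin, obsize, hd_abs, hu_abs, use_global,
                        seg_t0, seg_t1, seg_maj, seg_node)
        scattered = False
        terminated = False
        for si in range(nseg):
            M = seg_maj[si]
            t = seg_t0[si]
            while True:
                state, u = rng_next(state)
                t -= math.log(1.0 - u) / M
                if t >= seg_t1[si]:
                    break
                qx = ox + dx * t
                qy = oy + dy * t
                qz = oz + dz * t
                eval_props(qx, qy, qz, v0, v1, v2, v3, vmeta, bproxy, bform,
                           bxs_off, bcf_off, xs, coef, tfp, row)
                sigt = row[O_SIGT]
                if sigt > M * (1.0 + 1e-6) + 1e-12:
                    raise ValueError("majorant violation: extinction exceeds "
                                     "the node's stored bound")
                sign = M - sigt
                ca = (wr * row[O_SIGA] + wg * row[O_SIGA + 1]
                      + wb * row[O_SIGA + 2])
                cn = (wr + wg + wb) * sign
                cvs = (wr * row[O_SVS] + wg * row[O_SVS + 1]
                       + wb * row[O_SVS + 2])
                cfs = (wr * row[O_SFS] + wg * row[O_SFS + 1]
                       + wb * row[O_SFS + 2])
                ctot = ca + cn + cvs + cfs
                if ctot <= 0.0:
                    continue
                state, u2 = rng_next(state)
                pick = u2 * ctot
                if pick < ca:  # absorption: opacity-weighted emission
                    inv = 1.0 / (M * (ca / ctot))
                    Lr += wr * row[O_SIGA] * inv * row[O_LE]
                    Lg += wg * row[O_SIGA + 1] * inv * row[O_LE + 1]
                    Lb += wb * row[O_SIGA + 2] * inv * row[O_LE + 2]
                    terminated = True
                    break
                elif pick < ca + cn:  # null collision
                    # per-channel ratio sigma_n,c / (M * p_n) with the
                    # history-aware p_n; sigma_n is channel-uniform
                    pr = cn / ctot
                    wr = wr * sign / (M * pr)
                    wg = wg * sign / (M * pr)
                    wb = wb * sign / (M * pr)
                    continue
                else:
                    is_surface = pick >= ca + cn + cvs
                    if is_surface:
                        pr = cfs / ctot
                        wr = wr * row[O_SFS] / (M * pr)
                        wg = wg * row[O_SFS + 1] / (M * pr)
                        wb = wb * row[O_SFS + 2] / (M * pr)
                        if chan == 0:
                            wfrac = row[O_W]
                            wr *= row[O_A] / wfrac
                            wg *= row[O_A + 1] / wfrac
                            wb *= row[O_A + 2] / wfrac
                        gx = row[O_GRAD]
                        gy = row[O_GRAD + 1]
                        gz = row[O_GRAD + 2]
                        gm = math.sqrt(gx * gx + gy * gy + gz * gz)
                        # outward normal of dense structures: -gradient
                        nx = -gx / gm
                        ny = -gy / gm
                        nz = -gz / gm
                        if dx * nx + dy * ny + dz * nz >= 0.0:
                            # back-side incidence: fully absorbed
                            terminated = True
                            break
                        kind = int(row[O_KIND])
                        rough = row[O_ROUGH]
                        state, ar, ag, ab = _nee(
                            qx, qy, qz, dx, dy, dz, True, nx, ny, nz, kind,
                            rough, 0.0, wr, wg, wb, shadow_a, v0, v1, v2, v3,
                            vmeta, bproxy, bform, bxs_off, bcf_off, xs, coef,
                            tfp, max_ext, level_off, leaf_level, obmin,
                            obsize, hd_abs, hu_abs, use_global, ltype, lrgb,
                            lpos, envmap, sseg_t0, sseg_t1, sseg_maj,
                            sseg_node, srow, state)
                        Lr += ar
                        Lg += ag
                        Lb += ab
                        if kind == 1 or kind == 2:
                            e = _lobe_exponent(rough)
                            dn = dx * nx + dy * ny + dz * nz
                            rx = dx - 2.0 * dn * nx
                            ry = dy - 2.0 * dn * ny
                            rz = dz - 2.0 * dn * nz
                            state, u1 = rng_next(state)
                            state, u3 = rng_next(state)
                            ct = u1 ** (1.0 / (e + 1.0))
                            st = math.sqrt(max(0.0, 1.0 - ct * ct))
                            phi = 2.0 * math.pi * u3
                            tx, ty, tz, vx_, vy_, vz_ = _onb(rx, ry, rz)
                            ndx = ct * rx + st * (math.cos(phi) * tx
                                                  + math.sin(phi) * vx_)
                            ndy = ct * ry + st * (math.cos(phi) * ty
                                                  + math.sin(phi) * vy_)
                            ndz = ct * rz + st * (math.cos(phi) * tz
                                                  + math.sin(phi) * vz_)
                            cos_o = ndx * nx + ndy * ny + ndz * nz
                            if cos_o <= 0.0:
                                terminated = True  # absorbed by the surface
                                break
                            wgt = (e + 2.0) / (e + 1.0) * cos_o
                            wr *= wgt
                            wg *= wgt
                            wb *= wgt
                        else:
                            state, ndx, ndy, ndz = _cosine_sample(nx, ny, nz,
                                                                  state)
                    else:  # volumetric scattering
                        pr = cvs / ctot
                        wr = wr * row[O_SVS] / (M * pr)
                        wg = wg * row[O_SVS + 1] / (M * pr)
                        wb = wb * row[O_SVS + 2] / (M * pr)
                        if chan == 0:
                            wfrac = row[O_W]
                            wr *= row[O_S] / wfrac
                            wg *= row[O_S + 1] / wfrac
                            wb *= row[O_S + 2] / wfrac
                        g = row[O_G]
                        state, ar, ag, ab = _nee(
                            qx, qy, qz, dx, dy, dz, False, 0.0, 0.0, 1.0, 0,
                            0.0, g, wr, wg, wb, shadow_a, v0, v1, v2, v3,
                            vmeta, bproxy, bform, bxs_off, bcf_off, xs, coef,
                            tfp, max_ext, level_off, leaf_level, obmin,
                            obsize, hd_abs, hu_abs, use_global, ltype, lrgb,
                            lpos, envmap, sseg_t0, sseg_t1, sseg_maj,
                            sseg_node, srow, state)
                        Lr += ar
                        Lg += ag
                        Lb += ab
                        state, ndx, ndy, ndz = _hg_sample(g, dx, dy, dz,
                                                          state)
                    nscat += 1
                    if nscat > max_bounces:
                        terminated = True
                        break
                    if nscat >= rr_start:
                        wmax = wr
                        if wg > wmax:
                            wmax = wg
                        if wb > wmax:
                            wmax = wb
                        p = wmax
                        if p < 0.05:
                            p = 0.05
                        if p > 0.95:
                            p = 0.95
                        state, urr = rng_next(state)
                        if urr > p:
                            terminated = True
                            break
                        wr /= p
                        wg /= p
                        wb /= p
                    ox = qx
                    oy = qy
                    oz = qz
                    dx = ndx
                    dy = ndy
                    dz = ndz
                    scattered = True
                    break
            if scattered or terminated:
                break
        if terminated:
            break
        if not scattered:
            # passed through every segment without a real collision
            if nscat == 0:
                er, eg, eb = _escape_env(dx, dy, dz, ltype, lrgb, envmap)
                Lr += wr * er
                Lg += wg * eg
                Lb += wb * eb
            break
    if not (math.isfinite(Lr) and math.isfinite(Lg) and math.isfinite(Lb)):
        raise FloatingPointError("non-finite radiance in path tracer")
    return state, Lr, Lg, Lb


@njit(cache=True)
def render_kernel(cpos, cfwd, cright, cup, tanf, width, height, spp,
                  base_sample, seed, v0, v1, v2, v3, vmeta, bproxy, bform,
                  bxs_off, bcf_off, xs, coef, tfp, max_ext, level_off,
                  leaf_level, obmin, obsize, hd_abs, hu_abs, use_global,
                  ltype, lrgb, lpos, envmap, shadow_a, max_bounces, rr_start,
                  out_sum, out_sumsq):
    """Accumulate spp per-pixel radiance samples (sum and sum of squares)."""
    seg_t0 = np.empty(_MAX_SEG)
    seg_t1 = np.empty(_MAX_SEG)
    seg_maj = np.empty(_MAX_SEG)
    seg_node = np.empty(_MAX_SEG, dtype=np.int64)
    sseg_t0 = np.empty(_MAX_SEG)
    sseg_t1 = np.empty(_MAX_SEG)
    sseg_maj = np.empty(_MAX_SEG)
    sseg_node = np.empty(_MAX_SEG, dtype=np.int64)
    row = np.empty(NOUT)
    srow = np.empty(NOUT)
    aspect = width / height
    ns = int(math.sqrt(spp))
    if ns * ns != spp:
        ns = 0
    for j in range(height):
        for i in range(width):
            for s in range(spp):
                state = rng_init(seed, j * width + i, base_sample + s)
                state, ju = rng_next(state)
                state, jv = rng_next(state)
                if ns > 0:
                    ju = ((s % ns) + ju) / ns
                    jv = ((s // ns) + jv) / ns
                px = (2.0 * (i + ju) / width - 1.0) * tanf * aspect
                py = (1.0 - 2.0 * (j + jv) / height) * tanf
                ddx = cfwd[0] + px * cright[0] + py * cup[0]
                ddy = cfwd[1] + px * cright[1] + py * cup[1]
                ddz = cfwd[2] + px * cright[2] + py * cup[2]
                inv = 1.0 / math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                state, lr, lg, lb = trace_path(
                    cpos[0], cpos[1], cpos[2], ddx * inv, ddy * inv,
                    ddz * inv, v0, v1, v2, v3, vmeta, bproxy, bform, bxs_off,
                    bcf_off, xs, coef, tfp, max_ext, level_off, leaf_level,
                    obmin, obsize, hd_abs, hu_abs, use_global, ltype, lrgb,
                    lpos, envmap, shadow_a, max_bounces, rr_start, seg_t0,
                    seg_t1, seg_maj, seg_node, sseg_t0, sseg_t1, sseg_maj,
                    sseg_node, row, srow, state)
                out_sum[j, i, 0] += lr
                out_sum[j, i, 1] += lg
                out_sum[j, i, 2] += lb
                out_sumsq[j, i, 0] += lr * lr
                out_sumsq[j, i, 1] += lg * lg
                out_sumsq[j, i, 2] += lb * lb
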