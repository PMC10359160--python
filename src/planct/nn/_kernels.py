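"""Numba-compiled inner loops for the convolution and grid-sampling ops.

Kernels are dtype-generic (specialized lazily for float32 training and
float64 gradient checks) and single-threaded: one optimization step works on
one patch, and deployment targets are single-CPU nodes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3d_fwd(xp, w, out):
    """out[co] += sum_ci,k w[co,ci,k] * xp[ci, shifted k]; xp is pre-padded."""
    cout, cin, kx, ky, kz = w.shape
    nx, ny, nz = out.shape[1], out.shape[2], out.shape[3]
    for co in range(cout):
        for ci in range(cin):
            for dx in range(kx):
                for dy in range(ky):
                    for dz in range(kz):
                        wv = w[co, ci, dx, dy, dz]
                        if wv == 0.0:
                            continue
                        for a in range(nx):
                            for b in range(ny):
                                for c in range(nz):
                                    out[co, a, b, c] += (
                                        wv * xp[ci, a + dx, b + dy, c + dz])


@njit(cache=True, fastmath=True)
def conv3d_bwd_dx(g, w, dxp):
    """Scatter the output gradient through the kernel into padded dx."""
    cout, cin, kx, ky, kz = w.shape
    nx, ny, nz = g.shape[1], g.shape[2], g.shape[3]
    for co in range(cout):
        for ci in range(cin):
            for dx in range(kx):
                for dy in range(ky):
                    for dz in range(kz):
                        wv = w[co, ci, dx, dy, dz]
                        for a in range(nx):
                            for b in range(ny):
                                for c in range(nz):
                                    dxp[ci, a + dx, b + dy, c + dz] += (
                                        wv * g[co, a, b, c])


@njit(cache=True, fastmath=True)
def conv3d_bwd_dw(g, xp, dw):
    """dw[co,ci,k] = sum_p g[co,p] * xp[ci, p + k]."""
    cout, cin, kx, ky, kz = dw.shape
    nx, ny, nz = g.shape[1], g.shape[2], g.shape[3]
    zero = g[0, 0, 0, 0] - g[0, 0, 0, 0]  # dtype-matched accumulator seed
    for co in range(cout):
        for ci in range(cin):
            for dx in range(kx):
                for dy in range(ky):
                    for dz in range(kz):
                        s = zero
                        for a in range(nx):
                            for b in range(ny):
                                for c in range(nz):
                                    s += g[co, a, b, c] * xp[ci, a + dx,
                                                             b + dy, c + dz]
                        dw[co, ci, dx, dy, dz] = s


@njit(cache=True, fastmath=True)
def grid_sample_fwd(f, disp, out, i0, frac, inrange):
    """Trilinear sampling of f at index+disp with clamped (replicate) edges.

    Fills ``out`` (C, nx, ny, nz), integer corner bases ``i0`` (3, ...),
    fractions ``frac`` (3, ...) and the unclamped-in-domain flags ``inrange``
    (3, ...) reused by the backward pass.
    """
    c = f.shape[0]
    nx, ny, nz = f.shape[1], f.shape[2], f.shape[3]
    dims = (nx, ny, nz)
    for a in range(nx):
        for b in range(ny):
            for d in range(nz):
                base = (a, b, d)
                for ax in range(3):
                    co = base[ax] + disp[ax, a, b, d]
                    inrange[ax, a, b, d] = (co > 0.0) and (co < dims[ax] - 1.0)
                    if co < 0.0:
                        co = 0.0
                    elif co > dims[ax] - 1.0:
                        co = dims[ax] - 1.0
                    lo = int(np.floor(co))
                    if lo > dims[ax] - 2:
                        lo = dims[ax] - 2
                    i0[ax, a, b, d] = lo
                    frac[ax, a, b, d] = co - lo
                x0 = i0[0, a, b, d]
                y0 = i0[1, a, b, d]
                z0 = i0[2, a, b, d]
                tx = frac[0, a, b, d]
                ty = frac[1, a, b, d]
                tz = frac[2, a, b, d]
                for ch in range(c):
                    c000 = f[ch, x0, y0, z0]
                    c001 = f[ch, x0, y0, z0 + 1]
                    c010 = f[ch, x0, y0 + 1, z0]
                    c011 = f[ch, x0, y0 + 1, z0 + 1]
                    c100 = f[ch, x0 + 1, y0, z0]
                    c101 = f[ch, x0 + 1, y0, z0 + 1]
                    c110 = f[ch, x0 + 1, y0 + 1, z0]
                    c111 = f[ch, x0 + 1, y0 + 1, z0 + 1]
                    c00 = c000 * (1 - tz) + c001 * tz
                    c01 = c010 * (1 - tz) + c011 * tz
                    c10 = c100 * (1 - tz) + c101 * tz
                    c11 = c110 * (1 - tz) + c111 * tz
                    c0 = c00 * (1 - ty) + c01 * ty
                    c1 = c10 * (1 - ty) + c11 * ty
                    out[ch, a, b, d] = c0 * (1 - tx) + c1 * tx


@njit(cache=True, fastmath=True)
def grid_sample_bwd(g, f, i0, frac, inrange, need_df, need_dd, df, dd):
    """Gradients of trilinear sampling wrt the field and the displacement."""
    c = f.shape[0]
    nx, ny, nz = g.shape[1], g.shape[2], g.shape[3]
    for a in range(nx):
        for b in range(ny):
            for d in range(nz):
                x0 = i0[0, a, b, d]
                y0 = i0[1, a, b, d]
                z0 = i0[2, a, b, d]
                tx = frac[0, a, b, d]
                ty = frac[1, a, b, d]
                tz = frac[2, a, b, d]
                for ch in range(c):
                    gv = g[ch, a, b, d]
                    if need_df:
                        df[ch, x0, y0, z0] += gv * (1 - tx) * (1 - ty) * (1 - tz)
                        df[ch, x0, y0, z0 + 1] += gv * (1 - tx) * (1 - ty) * tz
                        df[ch, x0, y0 + 1, z0] += gv * (1 - tx) * ty * (1 - tz)
                        df[ch, x0, y0 + 1, z0 + 1] += gv * (1 - tx) * ty * tz
                        df[ch, x0 + 1, y0, z0] += gv * tx * (1 - ty) * (1 - tz)
                        df[ch, x0 + 1, y0, z0 + 1] += gv * tx * (1 - ty) * tz
                        df[ch, x0 + 1, y0 + 1, z0] += gv * tx * ty * (1 - tz)
                        df[ch, x0 + 1, y0 + 1, z0 + 1] += gv * tx * ty * tz
                    if need_dd:
                        c000 = f[ch, x0, y0, z0]
                        c001 = f[ch, x0, y0, z0 + 1]
                        c010 = f[ch, x0, y0 + 1, z0]
                        c011 = f[ch, x0, y0 + 1, z0 + 1]
                        c100 = f[ch, x0 + 1, y0, z0]
                        c101 = f[ch, x0 + 1, y0, z0 + 1]
                        c110 = f[ch, x0 + 1, y0 + 1, z0]
                        c111 = f[ch, x0 + 1, y0 + 1, z0 + 1]
                        if inrange[0, a, b, d]:
                            dd[0, a, b, d] += gv * (
                                (c100 - c000) * (1 - ty) * (1 - tz)
                                + (c101 - c001) * (1 - ty) * tz
                                + (c110 - c010) * ty * (1 - tz)
                                + (c111 - c011) * ty * tz)
                        if inrange[1, a, b, d]:
                            dd[1, a, b, d] += gv * (
                                (c010 - c000) * (1 - tx) * (1 - tz)
                                + (c011 - c001) * (1 - tx) * tz
                                + (c110 - c100) * tx * (1 - tz)
                                + (c111 - c101) * tx * tz)
                        if inrange[2, a, b, d]:
                            dd[2, a, b, d] += gv * (
                                (c001 - c000) * (1 - tx) * (1 - ty)
                                + (c011 - c010) * (1 - tx) * ty
                                + (c101 - c100) * tx * (1 - ty)
                                + (c111 - c110) * tx * ty)
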