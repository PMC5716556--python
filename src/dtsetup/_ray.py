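"""Numba ray-marching kernel for cone-beam line integrals."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def raycast(mu, src, dirs, t0, t1, step):  # pragma: no cover - exercised via projection tests
    """Integrate ``mu`` (index-space trilinear) along rays.

    ``src``: ray origin in continuous index coordinates (3,).
    ``dirs``: per-ray direction in index coords per mm of world path (n, 3).
    ``t0``/``t1``: world-path clip range (mm) of each ray against the grid.
    ``step``: nominal world sampling step (mm).  Returns per-ray integrals
    (mu * mm) using midpoint sampling.
    """
    n = dirs.shape[0]
    out = np.zeros(n)
    nx, ny, nz = mu.shape
    for i in range(n):
        a = t0[i]
        b = t1[i]
        if b - a <= 1e-9:
            continue
        m = int(np.ceil((b - a) / step))
        dt = (b - a) / m
        dx = dirs[i, 0]
        dy = dirs[i, 1]
        dz = dirs[i, 2]
        sx = src[0] + a * dx
        sy = src[1] + a * dy
        sz = src[2] + a * dz
        acc = 0.0
        for k in range(m):
            t = (k + 0.5) * dt
            x = sx + t * dx
            y = sy + t * dy
            z = sz + t * dz
            if x < 0.0 or y < 0.0 or z < 0.0:
                continue
            ix = int(x)
            iy = int(y)
            iz = int(z)
            if ix >= nx - 1:
                if x > nx - 1.0:
                    continue
                ix = nx - 2
            if iy >= ny - 1:
                if y > ny - 1.0:
                    continue
                iy = ny - 2
            if iz >= nz - 1:
                if z > nz - 1.0:
                    continue
                iz = nz - 2
            fx = x - ix
            fy = y - iy
            fz = z - iz
            c00 = mu[ix, iy, iz] * (1 - fx) + mu[ix + 1, iy, iz] * fx
            c10 = mu[ix, iy + 1, iz] * (1 - fx) + mu[ix + 1, iy + 1, iz] * fx
            c01 = mu[ix, iy, iz + 1] * (1 - fx) + mu[ix + 1, iy, iz + 1] * fx
            c11 = mu[ix, iy + 1, iz + 1] * (1 - fx) + mu[ix + 1, iy + 1, iz + 1] * fx
            c0 = c00 * (1 - fy) + c10 * fy
            c1 = c01 * (1 - fy) + c11 * fy
            acc += c0 * (1 - fz) + c1 * fz
        out[i] = acc * dt
    return out
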