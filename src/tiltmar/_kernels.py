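"""Numba kernels for fan-beam projection and backprojection.

All distances are in cm; images are (rows, cols) with the world origin at the
image center, row 0 anterior (+y), column index growing with +x.  The source
for view angle beta sits at ``sid * (cos beta, sin beta)``; channel k fires
along the central direction rotated counter-clockwise by ``gammas[k]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OPTS = dict(cache=True, fastmath=True, nogil=True)


@njit(**_OPTS)
def fan_project(img, px, sid, gammas, betas, fov, step):
    """Ray-driven line integrals with bilinear sampling; returns (nv, nc)."""
    nv = betas.shape[0]
    nc = gammas.shape[0]
    out = np.zeros((nv, nc))
    n, m = img.shape
    ci = (n - 1) / 2.0
    cj = (m - 1) / 2.0
    ns = int(2.0 * fov / step) + 1
    for iv in range(nv):
        b = betas[iv]
        sx = sid * np.cos(b)
        sy = sid * np.sin(b)
        cdx = -np.cos(b)
        cdy = -np.sin(b)
        for ic in range(nc):
            g = gammas[ic]
            cg = np.cos(g)
            sg = np.sin(g)
            dx = cg * cdx - sg * cdy
            dy = sg * cdx + cg * cdy
            tc = -(sx * dx + sy * dy)  # closest approach to isocenter
            acc = 0.0
            t = tc - fov
            for _ in range(ns):
                xx = sx + t * dx
                yy = sy + t * dy
                fi = ci - yy / px
                fj = cj + xx / px
                i0 = int(np.floor(fi))
                j0 = int(np.floor(fj))
                if 0 <= i0 < n - 1 and 0 <= j0 < m - 1:
                    wi = fi - i0
                    wj = fj - j0
                    acc += (img[i0, j0] * (1 - wi) * (1 - wj)
                            + img[i0, j0 + 1] * (1 - wi) * wj
                            + img[i0 + 1, j0] * wi * (1 - wj)
                            + img[i0 + 1, j0 + 1] * wi * wj)
                t += step
            out[iv, ic] = acc * step
    return out


@njit(**_OPTS)
def fan_project_labels(labels, n_mat, px, sid, gammas, betas, fov, step):
    """Per-material path lengths (n_mat, nv, nc) by nearest-neighbor sampling."""
    nv = betas.shape[0]
    nc = gammas.shape[0]
    out = np.zeros((n_mat, nv, nc))
    n, m = labels.shape
    ci = (n - 1) / 2.0
    cj = (m - 1) / 2.0
    ns = int(2.0 * fov / step) + 1
    for iv in range(nv):
        b = betas[iv]
        sx = sid * np.cos(b)
        sy = sid * np.sin(b)
        cdx = -np.cos(b)
        cdy = -np.sin(b)
        for ic in range(nc):
            g = gammas[ic]
            cg = np.cos(g)
            sg = np.sin(g)
            dx = cg * cdx - sg * cdy
            dy = sg * cdx + cg * cdy
            tc = -(sx * dx + sy * dy)
            t = tc - fov
            for _ in range(ns):
                xx = sx + t * dx
                yy = sy + t * dy
                i0 = int(np.rint(ci - yy / px))
                j0 = int(np.rint(cj + xx / px))
                if 0 <= i0 < n and 0 <= j0 < m:
                    lab = labels[i0, j0]
                    out[lab, iv, ic] += step
                t += step
    return out


@njit(**_OPTS)
def fan_backproject(q, px, n, m, sid, gammas, betas):
    """Distance-weighted backprojection of filtered data q (nv, nc)."""
    nv, nc = q.shape
    out = np.zeros((n, m))
    ci = (n - 1) / 2.0
    cj = (m - 1) / 2.0
    g0 = gammas[0]
    dg = gammas[1] - gammas[0]
    dbeta = 2.0 * np.pi / nv
    for iv in range(nv):
        b = betas[iv]
        sx = sid * np.cos(b)
        sy = sid * np.sin(b)
        cdx = -np.cos(b)
        cdy = -np.sin(b)
        for i in range(n):
            yy = (ci - i) * px
            for j in range(m):
                xx = (j - cj) * px
                vx = xx - sx
                vy = yy - sy
                l2 = vx * vx + vy * vy
                gp = np.arctan2(cdx * vy - cdy * vx, cdx * vx + cdy * vy)
                f = (gp - g0) / dg
                k = int(np.floor(f))
                if 0 <= k < nc - 1:
                    w = f - k
                    val = q[iv, k] * (1 - w) + q[iv, k + 1] * w
                    out[i, j] += dbeta * val / l2
    return out


@njit(**_OPTS)
def fan_backproject_adjoint(sino, px, n, m, sid, gammas, betas, fov, step):
    """Exact adjoint of :func:`fan_project` (bilinear splat along rays)."""
    nv, nc = sino.shape
    out = np.zeros((n, m))
    ci = (n - 1) / 2.0
    cj = (m - 1) / 2.0
    ns = int(2.0 * fov / step) + 1
    for iv in range(nv):
        b = betas[iv]
        sx = sid * np.cos(b)
        sy = sid * np.sin(b)
        cdx = -np.cos(b)
        cdy = -np.sin(b)
        for ic in range(nc):
            val = sino[iv, ic] * step
            if val == 0.0:
                continue
            g = gammas[ic]
            cg = np.cos(g)
            sg = np.sin(g)
            dx = cg * cdx - sg * cdy
            dy = sg * cdx + cg * cdy
            tc = -(sx * dx + sy * dy)
            t = tc - fov
            for _ in range(ns):
                xx = sx + t * dx
                yy = sy + t * dy
                fi = ci - yy / px
                fj = cj + xx / px
                i0 = int(np.floor(fi))
                j0 = int(np.floor(fj))
                if 0 <= i0 < n - 1 and 0 <= j0 < m - 1:
                    wi = fi - i0
                    wj = fj - j0
                    out[i0, j0] += val * (1 - wi) * (1 - wj)
                    out[i0, j0 + 1] += val * (1 - wi) * wj
                    out[i0 + 1, j0] += val * wi * (1 - wj)
                    out[i0 + 1, j0 + 1] += val * wi * wj
                t += step
    return out
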