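"""Numba-compiled finite-difference kernels (internal).

All kernels operate on C-contiguous float64 arrays.  The z axis is the last
(fastest) axis so the two out-of-plane neighbours of the 7-point stencil are
unit-stride loads.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True, fastmath=True)
def lap_periodic(f, inv_h2, out):  # pragma: no cover - exercised via wrappers
    nx, ny, nz = f.shape
    for i in range(nx):
        im = i - 1 if i > 0 else nx - 1
        ip = i + 1 if i < nx - 1 else 0
        for j in range(ny):
            jm = j - 1 if j > 0 else ny - 1
            jp = j + 1 if j < ny - 1 else 0
            for k in range(nz):
                km = k - 1 if k > 0 else nz - 1
                kp = k + 1 if k < nz - 1 else 0
                out[i, j, k] = (f[im, j, k] + f[ip, j, k]
                                + f[i, jm, k] + f[i, jp, k]
                                + f[i, j, km] + f[i, j, kp]
                                - 6.0 * f[i, j, k]) * inv_h2


@nb.njit(cache=True, fastmath=True)
def lap_dirichlet_z(f, inv_h2, ghost_lo, ghost_hi, out):  # pragma: no cover
    # x, y wrap; beyond the z faces the field is clamped to the ghost constants
    nx, ny, nz = f.shape
    for i in range(nx):
        im = i - 1 if i > 0 else nx - 1
        ip = i + 1 if i < nx - 1 else 0
        for j in range(ny):
            jm = j - 1 if j > 0 else ny - 1
            jp = j + 1 if j < ny - 1 else 0
            for k in range(nz):
                fzm = ghost_lo if k == 0 else f[i, j, k - 1]
                fzp = ghost_hi if k == nz - 1 else f[i, j, k + 1]
                out[i, j, k] = (f[im, j, k] + f[ip, j, k]
                                + f[i, jm, k] + f[i, jp, k]
                                + fzm + fzp - 6.0 * f[i, j, k]) * inv_h2


@nb.njit(cache=True, fastmath=True)
def euler_update(f, lap1, lap2, active, dt, d, alpha, beta):  # pragma: no cover
    """In-place explicit Euler step: f += dt·(−f^α(1−f)^β·d·Δf − Δ²f).

    ``active`` masks out frozen nodes and Dirichlet planes.  α = β = 1 is
    special-cased to keep the hot loop free of pow calls.
    """
    n = f.size
    ff = f.reshape(n)
    l1 = lap1.reshape(n)
    l2 = lap2.reshape(n)
    aa = active.reshape(n)
    simple = alpha == 1.0 and beta == 1.0
    for idx in range(n):
        if aa[idx]:
            fi = ff[idx]
            if simple:
                kern = fi * (1.0 - fi)
            else:
                kern = fi ** alpha * (1.0 - fi) ** beta
            ff[idx] = fi + dt * (-kern * d * l1[idx] - l2[idx])
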