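"""Numba inner loops for the overdamped Langevin integrator.

All kernels advance the Euler–Maruyama update

    z ← z + [β D(z) F(z) + D'(z)] dt + sqrt(2 D(z) dt) ξ

with F, D, D' linearly interpolated from a uniform grid.  Noise arrays are
pre-generated by the caller (numpy Generator), so all randomness is owned by
one seeded stream and the kernels are purely deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_reflecting(z, phase, noise, lo, inv_dx, F, D, dD, beta, dt,
                   zmin, zmax, out, out_start, out_stride):
    """Advance len(noise) steps with reflecting walls at zmin/zmax.

    Records every ``out_stride``-th step into ``out`` starting at
    ``out_start``; ``phase`` carries the recording phase across chunks.
    Returns (z, out_pos, phase, escape_step) with escape_step = -1 if the
    walk stayed on the grid, else the offending local step index.
    """
    n = noise.shape[0]
    npts = F.shape[0]
    out_pos = out_start
    for i in range(n):
        x = (z - lo) * inv_dx
        j = int(x)
        if j < 0:
            j = 0
        if j > npts - 2:
            j = npts - 2
        f = x - j
        Fz = F[j] + (F[j + 1] - F[j]) * f
        Dz = D[j] + (D[j + 1] - D[j]) * f
        dDz = dD[j] + (dD[j + 1] - dD[j]) * f
        z = z + (beta * Dz * Fz + dDz) * dt + np.sqrt(2.0 * Dz * dt) * noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        elif z > zmax:
            z = 2.0 * zmax - z
        if z < zmin or z > zmax:
            return z, out_pos, phase, i
        phase += 1
        if phase == out_stride:
            out[out_pos] = z
            out_pos += 1
            phase = 0
    return z, out_pos, phase, -1


@njit(cache=True)
def run_absorbing(z, noise, lo, inv_dx, F, D, dD, beta, dt,
                  zmin, zmax, absorb_lo, absorb_hi):
    """Advance until absorption or noise exhaustion.

    Boundaries flagged absorbing terminate the walk; the others reflect.
    Returns (z, steps_used, side) with side -1 (lower exit), +1 (upper exit)
    or 0 (still diffusing).
    """
    npts = F.shape[0]
    for i in range(noise.shape[0]):
        x = (z - lo) * inv_dx
        j = int(x)
        if j < 0:
            j = 0
        if j > npts - 2:
            j = npts - 2
        f = x - j
        Fz = F[j] + (F[j + 1] - F[j]) * f
        Dz = D[j] + (D[j + 1] - D[j]) * f
        dDz = dD[j] + (dD[j + 1] - dD[j]) * f
        z = z + (beta * Dz * Fz + dDz) * dt + np.sqrt(2.0 * Dz * dt) * noise[i]
        if absorb_lo and z <= zmin:
            return z, i + 1, -1
        if absorb_hi and z >= zmax:
            return z, i + 1, 1
        if z < zmin:
            z = 2.0 * zmin - z
        elif z > zmax:
            z = 2.0 * zmax - z
    return z, noise.shape[0], 0


@njit(cache=True)
def run_periodic(z, wraps, phase, noise, lo, inv_dx, F, D, dD, beta, dt,
                 zmin, zmax, out_z, out_w, out_start, out_stride):
    """Advance len(noise) steps on a periodic interval, tracking wrap count.

    Returns (z, wraps, out_pos, phase).
    """
    n = noise.shape[0]
    npts = F.shape[0]
    span = zmax - zmin
    out_pos = out_start
    for i in range(n):
        x = (z - lo) * inv_dx
        j = int(x)
        if j < 0:
            j = 0
        if j > npts - 2:
            j = npts - 2
        f = x - j
        Fz = F[j] + (F[j + 1] - F[j]) * f
        Dz = D[j] + (D[j + 1] - D[j]) * f
        dDz = dD[j] + (dD[j + 1] - dD[j]) * f
        z = z + (beta * Dz * Fz + dDz) * dt + np.sqrt(2.0 * Dz * dt) * noise[i]
        while z >= zmax:
            z -= span
            wraps += 1
        while z < zmin:
            z += span
            wraps -= 1
        phase += 1
        if phase == out_stride:
            out_z[out_pos] = z
            out_w[out_pos] = wraps
            out_pos += 1
            phase = 0
    return z, wraps, out_pos, phase
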