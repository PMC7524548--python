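"""Fused numba kernels for the coupled branching/synaptogenesis system.

These duplicate the numpy reference operators in :mod:`barrelmap.dynamics`
in a single pass over projections and hexes (a consistency test asserts
agreement to machine precision); they exist purely for speed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ANG = np.pi * np.arange(6) / 3.0
COS_J = np.cos(_ANG)
SIN_J = np.sin(_ANG)


@njit(cache=True)
def rates(a, c, gx, gy, divg, nbr, cosj, sinj, d, D, eps, alpha, beta, k, da, dc):
    """da/dt and dc/dt for all projections, written into preallocated da, dc.

    The competition divergence (term iv) is evaluated as the Gauss flux sum
    of the gradient-stencil field grad a_hat with zero flux through rim
    edges, so that sum_hex divJ*Omega telescopes to machine zero and mass is
    conserved exactly (see barrelmap.dynamics).
    """
    N, H = a.shape
    inv3d = 1.0 / (3.0 * d)
    lapc = 2.0 / (3.0 * d * d)
    chi_den = N - 1.0 if N > 1 else 1.0

    S = np.zeros(H)
    csum = np.zeros(H)
    for i in range(N):
        for h in range(H):
            S[h] += a[i, h]
            csum[h] += c[i, h]

    gSx = np.empty(H)
    gSy = np.empty(H)
    for h in range(H):
        s0 = S[h]
        ax = 0.0
        ay = 0.0
        for j in range(6):
            nb = nbr[h, j]
            if nb >= 0:
                df = S[nb] - s0
                ax += df * cosj[j]
                ay += df * sinj[j]
        gSx[h] = inv3d * ax
        gSy[h] = inv3d * ay

    lap_a = np.empty(H)
    gax = np.empty(H)
    gay = np.empty(H)
    ghx = np.empty(H)
    ghy = np.empty(H)
    for i in range(N):
        chi = eps[i] / chi_den
        for h in range(H):
            a0 = a[i, h]
            acc = 0.0
            ax = 0.0
            ay = 0.0
            for j in range(6):
                nb = nbr[h, j]
                if nb >= 0:
                    df = a[i, nb] - a0
                    acc += df
                    ax += df * cosj[j]
                    ay += df * sinj[j]
            lap_a[h] = lapc * acc
            gax[h] = inv3d * ax
            gay[h] = inv3d * ay
            ghx[h] = gSx[h] - gax[h]
            ghy[h] = gSy[h] - gay[h]
        for h in range(H):
            a0 = a[i, h]
            fx = 0.0
            for j in range(6):
                nb = nbr[h, j]
                if nb >= 0:
                    fx += ((ghx[nb] + ghx[h]) * cosj[j]
                           + (ghy[nb] + ghy[h]) * sinj[j])
            div_ghat = inv3d * fx
            divJ = (D * lap_a[h]
                    - a0 * divg[i, h]
                    - (gx[i, h] * gax[h] + gy[i, h] * gay[h])
                    + chi * (a0 * div_ghat + ghx[h] * gax[h] + ghy[h] * gay[h]))
            dci = -alpha * c[i, h] + beta * (1.0 - csum[h]) * a0 ** k
            dc[i, h] = dci
            da[i, h] = divJ - dci


@njit(cache=True)
def rk4_steps(a, c, gx, gy, divg, nbr, cosj, sinj, d, D, eps,
              alpha, beta, k, dt, nsteps, amax_abort):
    """Advance (a, c) in place by nsteps of classical RK4.

    Returns the number of completed steps; fewer than nsteps signals numerical
    instability (non-finite values or |a| exceeding amax_abort).
    """
    N, H = a.shape
    k1a = np.empty((N, H)); k1c = np.empty((N, H))
    k2a = np.empty((N, H)); k2c = np.empty((N, H))
    k3a = np.empty((N, H)); k3c = np.empty((N, H))
    k4a = np.empty((N, H)); k4c = np.empty((N, H))
    ta = np.empty((N, H)); tc = np.empty((N, H))
    for s in range(nsteps):
        rates(a, c, gx, gy, divg, nbr, cosj, sinj, d, D, eps, alpha, beta, k, k1a, k1c)
        for i in range(N):
            for h in range(H):
                ta[i, h] = a[i, h] + 0.5 * dt * k1a[i, h]
                tc[i, h] = c[i, h] + 0.5 * dt * k1c[i, h]
        rates(ta, tc, gx, gy, divg, nbr, cosj, sinj, d, D, eps, alpha, beta, k, k2a, k2c)
        for i in range(N):
            for h in range(H):
                ta[i, h] = a[i, h] + 0.5 * dt * k2a[i, h]
                tc[i, h] = c[i, h] + 0.5 * dt * k2c[i, h]
        rates(ta, tc, gx, gy, divg, nbr, cosj, sinj, d, D, eps, alpha, beta, k, k3a, k3c)
        for i in range(N):
            for h in range(H):
                ta[i, h] = a[i, h] + dt * k3a[i, h]
                tc[i, h] = c[i, h] + dt * k3c[i, h]
        rates(ta, tc, gx, gy, divg, nbr, cosj, sinj, d, D, eps, alpha, beta, k, k4a, k4c)
        ok = True
        sixth = dt / 6.0
        for i in range(N):
            for h in range(H):
                av = a[i, h] + sixth * (k1a[i, h] + 2.0 * k2a[i, h]
                                        + 2.0 * k3a[i, h] + k4a[i, h])
                cv = c[i, h] + sixth * (k1c[i, h] + 2.0 * k2c[i, h]
                                        + 2.0 * k3c[i, h] + k4c[i, h])
                a[i, h] = av
                c[i, h] = cv
                if not (np.isfinite(av) and np.isfinite(cv)) or abs(av) > amax_abort:
                    ok = False
        if not ok:
            return s + 1
    return nsteps
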