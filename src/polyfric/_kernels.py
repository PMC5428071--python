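"""Numba inner loops for the Langevin integrator and chain reconstruction.

All kernels are compiled with ``cache=True`` and without fastmath so that
results are bitwise reproducible from run to run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forces_into", "langevin_chunk", "reconstruct_positions", "reconstruct_r_series"]


@njit(cache=True)
def _forces_core(pos, F, bvec, rb, sigma, k_bond, theta0, k_bend, eps_dih, ev_A, ev_cut2, ev_min_sep):
    """Accumulate -grad V into F using the work arrays bvec, rb.

    Returns the largest squared bond length (for the stability check).
    """
    N = pos.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    # bond vectors + bond forces: V = k/2 (r - sigma)^2
    max_b2 = 0.0
    for i in range(N - 1):
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        bz = pos[i + 1, 2] - pos[i, 2]
        r2 = bx * bx + by * by + bz * bz
        if not (r2 < 1.0e12):
            return 1.0e30  # blown up / NaN; bail out
        if r2 > max_b2:
            max_b2 = r2
        r = np.sqrt(r2)
        bvec[i, 0] = bx
        bvec[i, 1] = by
        bvec[i, 2] = bz
        rb[i] = r
        f = k_bond * (r - sigma) / r
        F[i, 0] += f * bx
        F[i, 1] += f * by
        F[i, 2] += f * bz
        F[i + 1, 0] -= f * bx
        F[i + 1, 1] -= f * by
        F[i + 1, 2] -= f * bz

    # bends: V = k/2 (theta - theta0)^2 with theta at bead j between bonds
    # to beads j-1 and j+1; cos(theta) = -(b[j-1].b[j]) / (|b[j-1]||b[j]|)
    for j in range(1, N - 1):
        ux = -bvec[j - 1, 0]
        uy = -bvec[j - 1, 1]
        uz = -bvec[j - 1, 2]
        vx = bvec[j, 0]
        vy = bvec[j, 1]
        vz = bvec[j, 2]
        ru = rb[j - 1]
        rv = rb[j]
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1.0e-16:
            continue  # straight/folded: force undefined, measure zero
        s = np.sqrt(s2)
        theta = np.arccos(c)
        dVdcos = -k_bend * (theta - theta0) / s
        gax = vx / (ru * rv) - c * ux / (ru * ru)
        gay = vy / (ru * rv) - c * uy / (ru * ru)
        gaz = vz / (ru * rv) - c * uz / (ru * ru)
        gcx = ux / (ru * rv) - c * vx / (rv * rv)
        gcy = uy / (ru * rv) - c * vy / (rv * rv)
        gcz = uz / (ru * rv) - c * vz / (rv * rv)
        F[j - 1, 0] -= dVdcos * gax
        F[j - 1, 1] -= dVdcos * gay
        F[j - 1, 2] -= dVdcos * gaz
        F[j + 1, 0] -= dVdcos * gcx
        F[j + 1, 1] -= dVdcos * gcy
        F[j + 1, 2] -= dVdcos * gcz
        F[j, 0] += dVdcos * (gax + gcx)
        F[j, 1] += dVdcos * (gay + gcy)
        F[j, 2] += dVdcos * (gaz + gcz)

    # dihedrals: V = eps/2 (1 - cos 3 phi); dV/dphi = (3 eps / 2) sin 3 phi
    # sin(3 phi) computed from sin(phi), cos(phi) without calling atan2/sin
    if eps_dih != 0.0:
        for i in range(N - 3):
            b1x = bvec[i, 0]
            b1y = bvec[i, 1]
            b1z = bvec[i, 2]
            b2x = bvec[i + 1, 0]
            b2y = bvec[i + 1, 1]
            b2z = bvec[i + 1, 2]
            b3x = bvec[i + 2, 0]
            b3y = bvec[i + 2, 1]
            b3z = bvec[i + 2, 2]
            mx = b1y * b2z - b1z * b2y
            my = b1z * b2x - b1x * b2z
            mz = b1x * b2y - b1y * b2x
            nx = b2y * b3z - b2z * b3y
            ny = b2z * b3x - b2x * b3z
            nz = b2x * b3y - b2y * b3x
            m2 = mx * mx + my * my + mz * mz
            n2 = nx * nx + ny * ny + nz * nz
            if m2 < 1.0e-16 or n2 < 1.0e-16:
                continue
            b2n = rb[i + 1]
            cxx = my * nz - mz * ny
            cxy = mz * nx - mx * nz
            cxz = mx * ny - my * nx
            yv = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
            xv = mx * nx + my * ny + mz * nz
            h = np.sqrt(xv * xv + yv * yv)
            if h < 1.0e-16:
                continue
            sphi = yv / h
            cphi = xv / h
            s3 = sphi * (4.0 * cphi * cphi - 1.0)  # sin(3p) = sin p (4 cos^2 p - 1)
            dVdphi = 1.5 * eps_dih * s3
            g0 = -b2n / m2
            g3 = b2n / n2
            t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
            t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
            d0x = g0 * mx
            d0y = g0 * my
            d0z = g0 * mz
            d3x = g3 * nx
            d3y = g3 * ny
            d3z = g3 * nz
            d1x = -(1.0 + t1) * d0x + t2 * d3x
            d1y = -(1.0 + t1) * d0y + t2 * d3y
            d1z = -(1.0 + t1) * d0z + t2 * d3z
            d2x = t1 * d0x - (1.0 + t2) * d3x
            d2y = t1 * d0y - (1.0 + t2) * d3y
            d2z = t1 * d0z - (1.0 + t2) * d3z
            F[i, 0] -= dVdphi * d0x
            F[i, 1] -= dVdphi * d0y
            F[i, 2] -= dVdphi * d0z
            F[i + 1, 0] -= dVdphi * d1x
            F[i + 1, 1] -= dVdphi * d1y
            F[i + 1, 2] -= dVdphi * d1z
            F[i + 2, 0] -= dVdphi * d2x
            F[i + 2, 1] -= dVdphi * d2y
            F[i + 2, 2] -= dVdphi * d2z
            F[i + 3, 0] -= dVdphi * d3x
            F[i + 3, 1] -= dVdphi * d3y
            F[i + 3, 2] -= dVdphi * d3z

    # excluded volume: V = A [(sigma/r)^12 - (sigma/rc)^12], r < rc, |i-j| >= ev_min_sep
    if ev_A != 0.0 and ev_cut2 > 0.0:
        s2_ = sigma * sigma
        for i in range(N - ev_min_sep):
            for j in range(i + ev_min_sep, N):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < ev_cut2:
                    inv = s2_ / r2
                    s6 = inv * inv * inv
                    f = 12.0 * ev_A * s6 * s6 / r2
                    F[j, 0] += f * dx
                    F[j, 1] += f * dy
                    F[j, 2] += f * dz
                    F[i, 0] -= f * dx
                    F[i, 1] -= f * dy
                    F[i, 2] -= f * dz
    return max_b2


@njit(cache=True)
def forces_into(pos, F, sigma, k_bond, theta0, k_bend, eps_dih, ev_A, ev_cut2, ev_min_sep):
    """Single-shot force evaluation (allocates its own work arrays)."""
    N = pos.shape[0]
    bvec = np.empty((N - 1, 3))
    rb = np.empty(N - 1)
    _forces_core(pos, F, bvec, rb, sigma, k_bond, theta0, k_bend, eps_dih, ev_A, ev_cut2, ev_min_sep)


@njit(cache=True)
def langevin_chunk(
    pos,
    noise,
    mob_dt,
    sigma,
    k_bond,
    theta0,
    k_bend,
    eps_dih,
    ev_A,
    ev_cut2,
    ev_min_sep,
    max_bond2,
    stride,
    phase,
    frames,
    n_stored,
):
    """Advance ``noise.shape[0]`` Euler-Maruyama steps in place.

    ``noise`` must already be scaled by sqrt(2 kBT dt / xi0); ``mob_dt`` is
    dt/xi0.  A frame is stored into ``frames[n_stored]`` after step ``s``
    whenever ``(phase + s + 1) % stride == 0`` (``stride <= 0`` disables
    storage).  Returns ``(fail_step, n_stored)`` where ``fail_step`` is the
    in-chunk step index at which the integration blew up, or -1.
    """
    n = noise.shape[0]
    N = pos.shape[0]
    F = np.empty((N, 3))
    bvec = np.empty((N - 1, 3))
    rb = np.empty(N - 1)
    for s in range(n):
        b2 = _forces_core(
            pos, F, bvec, rb, sigma, k_bond, theta0, k_bend, eps_dih, ev_A, ev_cut2, ev_min_sep
        )
        if not (b2 < max_bond2):
            return s, n_stored
        for i in range(N):
            pos[i, 0] += F[i, 0] * mob_dt + noise[s, i, 0]
            pos[i, 1] += F[i, 1] * mob_dt + noise[s, i, 1]
            pos[i, 2] += F[i, 2] * mob_dt + noise[s, i, 2]
        if stride > 0 and (phase + s + 1) % stride == 0:
            for i in range(N):
                frames[n_stored, i, 0] = pos[i, 0]
                frames[n_stored, i, 1] = pos[i, 1]
                frames[n_stored, i, 2] = pos[i, 2]
            n_stored += 1
    return -1, n_stored


@njit(cache=True)
def reconstruct_positions(phis, sigma, theta0, out):
    """Build an N-bead chain from N-3 torsions with fixed bonds and bends.

    Canonical frame: bead 0 at the origin, bead 1 on +x, bead 2 in the
    xy-plane with positive y.  ``out`` has shape (N, 3).
    """
    n_dih = phis.shape[0]
    out[0, 0] = 0.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    out[1, 0] = sigma
    out[1, 1] = 0.0
    out[1, 2] = 0.0
    out[2, 0] = sigma + sigma * np.cos(np.pi - theta0)
    out[2, 1] = sigma * np.sin(np.pi - theta0)
    out[2, 2] = 0.0
    for i in range(n_dih):
        # NeRF placement of bead i+3 from beads i, i+1, i+2
        bcx = out[i + 2, 0] - out[i + 1, 0]
        bcy = out[i + 2, 1] - out[i + 1, 1]
        bcz = out[i + 2, 2] - out[i + 1, 2]
        rbc = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= rbc
        bcy /= rbc
        bcz /= rbc
        abx = out[i + 1, 0] - out[i, 0]
        aby = out[i + 1, 1] - out[i, 1]
        abz = out[i + 1, 2] - out[i, 2]
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        rn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= rn
        ny /= rn
        nz /= rn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        phi = phis[i]
        d0 = -sigma * np.cos(theta0)
        d1 = sigma * np.sin(theta0) * np.cos(phi)
        d2 = sigma * np.sin(theta0) * np.sin(phi)
        out[i + 3, 0] = out[i + 2, 0] + d0 * bcx + d1 * mx + d2 * nx
        out[i + 3, 1] = out[i + 2, 1] + d0 * bcy + d1 * my + d2 * ny
        out[i + 3, 2] = out[i + 2, 2] + d0 * bcz + d1 * mz + d2 * nz


@njit(cache=True)
def reconstruct_r_series(phi_frames, sigma, theta0):
    """End-to-end distance for each row of torsions in ``phi_frames``."""
    T, n_dih = phi_frames.shape
    N = n_dih + 3
    out = np.empty(T)
    pos = np.empty((N, 3))
    for t in range(T):
        reconstruct_positions(phi_frames[t], sigma, theta0, pos)
        dx = pos[N - 1, 0] - pos[0, 0]
        dy = pos[N - 1, 1] - pos[0, 1]
        dz = pos[N - 1, 2] - pos[0, 2]
        out[t] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out
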