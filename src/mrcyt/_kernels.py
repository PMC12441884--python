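"""Numba kernels: GPA mode integrals, exchange propagation, Monte-Carlo walkers.

All kernels work on sampled effective-gradient waveforms (piecewise constant
over steps of width ``dt``).  The Gaussian-phase-approximation (GPA) integrals
use the exact step update for the exponential kernel, so results are exact for
the sampled (piecewise-constant) waveform, not just O(dt) approximations.
Units follow the package convention: time ms, gradient mT/m, length um.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gpa_mode_integrals(g, dt, kappas):
    """Double integrals J_n = int_0^TE g(t) int_0^t g(t') exp(-kappa_n (t-t')) dt' dt.

    Exact for piecewise-constant g.  The GPA log-attenuation is
    ln S = -gamma^2 * sum_n B_n * J_n   (gamma and B_n applied by the caller).
    """
    n_t = g.shape[0]
    n_k = kappas.shape[0]
    out = np.zeros(n_k)
    for n in range(n_k):
        k = kappas[n]
        kdt = k * dt
        if kdt > 1e-10:
            e = np.exp(-kdt)
            a = (1.0 - e) / k          # int of exp(-k s) over one step
            c = (dt - a) / k           # step self-term double integral
        else:                          # series fallback for vanishing kappa
            e = 1.0 - kdt
            a = dt * (1.0 - 0.5 * kdt)
            c = 0.5 * dt * dt
        y = 0.0                        # y(t_k) = int_0^{t_k} g exp(-k (t_k - s)) ds
        acc = 0.0
        for t in range(n_t):
            gt = g[t]
            acc += gt * (y * a + gt * c)
            y = y * e + gt * a
        out[n] = acc
    return out


@njit(cache=True)
def gpa_step_sums(g, dt, kappas, weights):
    """Per-step increments r_k of sum_n B_n * J_n (see gpa_mode_integrals).

    sum(r) equals -ln S / gamma^2; r_k / dt is the instantaneous intracellular
    dephasing-rate profile (up to gamma^2) used by the exchange propagator.
    """
    n_t = g.shape[0]
    n_k = kappas.shape[0]
    r = np.zeros(n_t)
    for n in range(n_k):
        k = kappas[n]
        b = weights[n]
        kdt = k * dt
        if kdt > 1e-10:
            e = np.exp(-kdt)
            a = (1.0 - e) / k
            c = (dt - a) / k
        else:
            e = 1.0 - kdt
            a = dt * (1.0 - 0.5 * kdt)
            c = 0.5 * dt * dt
        y = 0.0
        for t in range(n_t):
            gt = g[t]
            r[t] += b * gt * (y * a + gt * c)
            y = y * e + gt * a
    return r


@njit(cache=True)
def exchange_propagate(rate_in, rate_ex, dt, k_in, k_out, v_in):
    """Propagate the two-compartment exchange system through the waveform.

    M' = A(t) M with A = [[-rate_in - k_in, k_out], [k_in, -rate_ex - k_out]],
    piecewise constant over each step; the step update is the exact 2x2 matrix
    exponential.  Returns M_in + M_ex at the echo time, starting from
    (v_in, 1 - v_in).  All rates in 1/ms.
    """
    m1 = v_in
    m2 = 1.0 - v_in
    for t in range(rate_in.shape[0]):
        a11 = -rate_in[t] - k_in
        a22 = -rate_ex[t] - k_out
        m = 0.5 * (a11 + a22)
        q2 = 0.25 * (a11 - a22) * (a11 - a22) + k_in * k_out
        q = np.sqrt(q2)
        em = np.exp(m * dt)
        qdt = q * dt
        if qdt > 1e-8:
            ch = np.cosh(qdt)
            shq = np.sinh(qdt) / q
        else:
            ch = 1.0 + 0.5 * qdt * qdt
            shq = dt * (1.0 + qdt * qdt / 6.0)
        e11 = em * (ch + shq * (a11 - m))
        e12 = em * (shq * k_out)
        e21 = em * (shq * k_in)
        e22 = em * (ch + shq * (a22 - m))
        n1 = e11 * m1 + e12 * m2
        n2 = e21 * m1 + e22 * m2
        m1 = n1
        m2 = n2
    return m1 + m2


@njit(cache=True)
def mc_sphere_signal(g, dt, radius, diffusivity, n_walkers, seed, restricted, gamma):
    """Monte-Carlo random walk dMRI signal for spins inside a reflecting sphere.

    Walkers start uniformly inside the sphere (at the origin when
    ``restricted`` is false, i.e. free diffusion), take Gaussian steps of std
    sqrt(2 D dt) per axis with specular reflection at the boundary, and
    accumulate phase phi += gamma * g(t) * x_mid * dt.  Returns |<exp(i phi)>|.
    """
    np.random.seed(seed)
    n_t = g.shape[0]
    sig = np.sqrt(2.0 * diffusivity * dt)
    r2max = radius * radius
    sum_c = 0.0
    sum_s = 0.0
    for _ in range(n_walkers):
        if restricted:
            while True:
                x = (2.0 * np.random.random() - 1.0) * radius
                y = (2.0 * np.random.random() - 1.0) * radius
                z = (2.0 * np.random.random() - 1.0) * radius
                if x * x + y * y + z * z <= r2max:
                    break
        else:
            x = 0.0
            y = 0.0
            z = 0.0
        phi = 0.0
        for t in range(n_t):
            nx = x + sig * np.random.normal()
            ny = y + sig * np.random.normal()
            nz = z + sig * np.random.normal()
            if restricted:
                it = 0
                while nx * nx + ny * ny + nz * nz > r2max and it < 16:
                    # intersection of segment (x,y,z)->(nx,ny,nz) with sphere
                    vx = nx - x
                    vy = ny - y
                    vz = nz - z
                    aa = vx * vx + vy * vy + vz * vz
                    bb = 2.0 * (x * vx + y * vy + z * vz)
                    cc = x * x + y * y + z * z - r2max
                    disc = bb * bb - 4.0 * aa * cc
                    if disc < 0.0 or aa == 0.0:
                        break
                    s = (-bb + np.sqrt(disc)) / (2.0 * aa)
                    if s < 0.0:
                        s = 0.0
                    elif s > 1.0:
                        s = 1.0
                    hx = x + s * vx
                    hy = y + s * vy
                    hz = z + s * vz
                    # reflect remaining displacement about the tangent plane
                    rx = (1.0 - s) * vx
                    ry = (1.0 - s) * vy
                    rz = (1.0 - s) * vz
                    nrm = np.sqrt(hx * hx + hy * hy + hz * hz)
                    if nrm == 0.0:
                        break
                    ux = hx / nrm
                    uy = hy / nrm
                    uz = hz / nrm
                    dot = rx * ux + ry * uy + rz * uz
                    x = hx
                    y = hy
                    z = hz
                    nx = hx + rx - 2.0 * dot * ux
                    ny = hy + ry - 2.0 * dot * uy
                    nz = hz + rz - 2.0 * dot * uz
                    it += 1
                if nx * nx + ny * ny + nz * nz > r2max:
                    # numerically stuck: clamp just inside the boundary
                    nrm = np.sqrt(nx * nx + ny * ny + nz * nz)
                    fac = radius * 0.999999 / nrm
                    nx *= fac
                    ny *= fac
                    nz *= fac
            phi += gamma * g[t] * 0.5 * (x + nx) * dt
            x = nx
            y = ny
            z = nz
        sum_c += np.cos(phi)
        sum_s += np.sin(phi)
    mc = sum_c / n_walkers
    ms = sum_s / n_walkers
    return np.sqrt(mc * mc + ms * ms)
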