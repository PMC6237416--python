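"""Numba-accelerated Euler-Maruyama inner loop.

The scalar kernel mirrors energy.batch_gradient term by term; dynamics
falls back to the vectorized numpy path when numba is unavailable.  The
kernel advances one pre-drawn noise block for all replicas and records
snapshots in place.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=True)
def _sstep(t):
    if t <= 0.0:
        return 0.0
    if t >= 1.0:
        return 1.0
    return t * t * (3.0 - 2.0 * t)


@njit(cache=True, fastmath=True)
def _dsstep(t):
    if t <= 0.0 or t >= 1.0:
        return 0.0
    return 6.0 * t * (1.0 - t)


@njit(cache=True, fastmath=True)
def step_block(
    X,  # (R, 14) in/out
    Y,  # (R, 2) in/out
    noise,  # (b, R, dim)
    b,
    naked,
    dt,
    D_dna,  # (14,) per-contact diffusion coefficients
    D_lobe,
    depth,  # (14,)
    flank,  # (14,)
    tilt,  # (14,)
    tk,  # (13,)
    mup,  # (13,)
    mum,  # (13,)
    temp,
    grip1,
    grip2,
    grip_mult,
    coupling_gap,  # closure_offset - lobe_coupling
    hbar,  # closure barrier
    strain,
    anchor,
    eps_elec,
    elec_w,
    wall_hw,
    wall_H,
    res_on,
    res_center,
    res_hw,
    res_k,
    ufloor_on,
    ufloor,
    ufloor_k,
    rec_every,
    step0,  # global step index before this block
    frame0,  # next frame slot
    Xs,  # (F, R, 14) out
    Ys,  # (F, R, 2) out
):
    R = X.shape[0]
    n = X.shape[1]
    sx = np.sqrt(2.0 * D_dna * dt)  # (14,)
    sy = np.sqrt(2.0 * D_lobe * dt)
    cx = D_dna * dt  # (14,)
    cy = D_lobe * dt
    two_pi = 2.0 * np.pi
    w2 = elec_w * elec_w
    frame = frame0
    for i in range(b):
        for r in range(R):
            y1 = Y[r, 0]
            y2 = Y[r, 1]
            gy1 = grip_mult * grip1 * np.pi * np.sin(two_pi * y1)
            gy2 = grip_mult * grip2 * np.pi * np.sin(two_pi * y2)
            u = y1 - y2
            dV = hbar * np.pi * np.sin(two_pi * u) + coupling_gap * _dsstep(u)
            if u < -0.25:
                dV -= 2.0 * 25.0 * (-(u + 0.25))
            elif u > 1.25:
                dV += 2.0 * 25.0 * (u - 1.25)
            gy1 += dV
            gy2 -= dV
            gy1 -= strain * _dsstep(y1 - anchor)
            if ufloor_on and u < ufloor:
                g = -2.0 * ufloor_k * (ufloor - u)
                gy1 += g
                gy2 -= g
            if naked:
                Y[r, 0] = y1 - gy1 * cy + sy * noise[i, r, 0]
                Y[r, 1] = y2 - gy2 * cy + sy * noise[i, r, 1]
                continue
            gX = np.zeros(n)
            for j in range(n):
                dev = X[r, j] - np.round(X[r, j])
                gX[j] = (
                    depth[j] * np.pi * np.sin(two_pi * X[r, j])
                    + flank[j] * _dsstep(abs(dev) / 0.2) / 0.2 * (1.0 if dev >= 0 else -1.0)
                    + tilt[j]
                )
            for m in range(n - 1):
                d = X[r, m + 1] - X[r, m]
                em = mum[m] + 0.5 * tk[m] * (d + 1.0) ** 2
                e0 = 0.5 * tk[m] * d * d
                ep = mup[m] + 0.5 * tk[m] * (d - 1.0) ** 2
                emin = min(em, min(e0, ep))
                wm = np.exp(-(em - emin) / temp)
                w0 = np.exp(-(e0 - emin) / temp)
                wp = np.exp(-(ep - emin) / temp)
                du = (
                    wm * tk[m] * (d + 1.0) + w0 * tk[m] * d + wp * tk[m] * (d - 1.0)
                ) / (wm + w0 + wp)
                gX[m + 1] += du
                gX[m] -= du
            xbar = 0.5 * (X[r, 8] + X[r, 9])
            rho = xbar - 0.5 * (y1 + y2)
            arho = abs(rho)
            if arho > wall_hw:
                dwall = 2.0 * wall_H * (arho - wall_hw) * (1.0 if rho > 0 else -1.0)
                gX[8] += 0.5 * dwall
                gX[9] += 0.5 * dwall
                gy1 -= 0.5 * dwall
                gy2 -= 0.5 * dwall
            r1 = xbar - y1
            delec = eps_elec * r1 / w2 * np.exp(-(r1 * r1) / (2.0 * w2))
            gX[8] += 0.5 * delec
            gX[9] += 0.5 * delec
            gy1 -= delec
            if res_on:
                dev = xbar - res_center
                adev = abs(dev)
                if adev > res_hw:
                    g = res_k * (adev - res_hw) * (1.0 if dev > 0 else -1.0)
                    gX[8] += g
                    gX[9] += g
            for j in range(n):
                X[r, j] = X[r, j] - gX[j] * cx[j] + sx[j] * noise[i, r, j]
            Y[r, 0] = y1 - gy1 * cy + sy * noise[i, r, n]
            Y[r, 1] = y2 - gy2 * cy + sy * noise[i, r, n + 1]
        step = step0 + i + 1
        if step % rec_every == 0:
            for r in range(R):
                for j in range(n):
                    Xs[frame, r, j] = X[r, j]
                Ys[frame, r, 0] = Y[r, 0]
                Ys[frame, r, 1] = Y[r, 1]
            frame += 1
    return frame
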