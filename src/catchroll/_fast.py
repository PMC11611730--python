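"""Numba-compiled inner kernels for the KMC hot loop.

``newton_equilibrate`` is the performance-critical twin of
:func:`catchroll.mechanics.equilibrate` (damped Newton on the two generalized
coordinates); the two must agree to solver tolerance, which the test suite
checks on randomized tether configurations.  The robust SciPy-backed solver
remains the fallback whenever the fast path fails to converge.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["newton_equilibrate", "tensions"]


@njit(cache=True, fastmath=False)
def _residual_jac(sub, u, L0, kappa, cx, th, fx_load, my_load, hc, R):
    """Generalized force residual (Fx, My) and 2x2 Jacobian."""
    ct = math.cos(th)
    st = math.sin(th)
    g1 = fx_load
    g2 = my_load
    j11 = 0.0
    j12 = 0.0
    j22 = 0.0
    n = L0.shape[0]
    for i in range(n):
        rx = R * (u[i, 0] * ct + u[i, 2] * st)
        ry = R * u[i, 1]
        rz = R * (-u[i, 0] * st + u[i, 2] * ct)
        ax = cx + rx
        ay = ry
        az = hc + rz
        dx = sub[i, 0] - ax
        dy = sub[i, 1] - ay
        dz = -az
        length = math.sqrt(dx * dx + dy * dy + dz * dz)
        ext = length - L0[i]
        if ext <= 0.0 or length <= 0.0:
            continue
        T = kappa[i] * ext
        inv_l = 1.0 / length
        dhx = dx * inv_l
        dhy = dy * inv_l
        dhz = dz * inv_l
        fx = T * dhx
        fz = T * dhz
        wx = rz
        wz = -rx
        g1 += fx
        g2 += wx * fx + wz * fz
        tl = T * inv_l
        kd = kappa[i]
        # quad(a, b) = a^T K b restricted to the x-z plane (w_y = 0)
        e_d = dhx
        w_d = wx * dhx + wz * dhz
        j11 -= kd * e_d * e_d + tl * (1.0 - e_d * e_d)
        j12 -= kd * e_d * w_d + tl * (wx - e_d * w_d)
        j22 -= kd * w_d * w_d + tl * ((wx * wx + wz * wz) - w_d * w_d)
        j22 += -rx * fx - rz * fz
    return g1, g2, j11, j12, j22


@njit(cache=True, fastmath=False)
def newton_equilibrate(
    sub, u, L0, kappa, cx0, th0, fx_load, my_load, hc, R, tol, max_iter
):
    """Damped Newton force balance.  Returns (cx, th, residual, converged)."""
    cx = cx0
    th = th0
    g1, g2, j11, j12, j22 = _residual_jac(
        sub, u, L0, kappa, cx, th, fx_load, my_load, hc, R
    )
    gn = max(abs(g1), abs(g2))
    cap = R if R > 1.0 else 1.0
    mu = 0.0  # Levenberg damping, raised when a plain Newton step stalls
    for _ in range(max_iter):
        if gn <= tol:
            return cx, th, gn, True
        a11 = j11 - mu
        a22 = j22 - mu
        det = a11 * a22 - j12 * j12
        if abs(det) > 1e-300:
            s1 = (-g1 * a22 + g2 * j12) / det
            s2 = (-a11 * g2 + j12 * g1) / det
        else:
            scale = 0.01 / max(1.0, gn)
            s1 = g1 * scale
            s2 = g2 * scale
        norm = max(abs(s1), abs(s2))
        if norm > cap:
            s1 *= cap / norm
            s2 *= cap / norm
        lam = 1.0
        improved = False
        for _bt in range(30):
            cx_n = cx + lam * s1
            th_n = th + lam * s2
            h1, h2, k11, k12, k22 = _residual_jac(
                sub, u, L0, kappa, cx_n, th_n, fx_load, my_load, hc, R
            )
            hn = max(abs(h1), abs(h2))
            if hn < gn:
                cx = cx_n
                th = th_n
                g1, g2, j11, j12, j22 = h1, h2, k11, k12, k22
                gn = hn
                improved = True
                break
            lam *= 0.5
        if improved:
            mu *= 0.25
        else:
            # stalled: damp the Jacobian and retry (tension-only springs make
            # the residual only piecewise-smooth)
            mu = 1.0 if mu == 0.0 else mu * 10.0
            if mu > 1e12:
                return cx, th, gn, False
    return cx, th, gn, gn <= tol


@njit(cache=True, fastmath=False)
def tensions(sub, u, L0, kappa, cx, th, hc, R):
    """Per-tether tensions (pN) at a given particle configuration."""
    ct = math.cos(th)
    st = math.sin(th)
    n = L0.shape[0]
    out = np.zeros(n)
    for i in range(n):
        ax = cx + R * (u[i, 0] * ct + u[i, 2] * st)
        ay = R * u[i, 1]
        az = hc + R * (-u[i, 0] * st + u[i, 2] * ct)
        dx = sub[i, 0] - ax
        dy = sub[i, 1] - ay
        length = math.sqrt(dx * dx + dy * dy + az * az)
        ext = length - L0[i]
        if ext > 0.0:
            out[i] = kappa[i] * ext
    return out
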