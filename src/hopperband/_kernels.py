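"""Compiled inner loops of the transport solver.

One fused kernel evaluates the full conservative right-hand side on the
(x, ng, nh) product grid: donor-cell upwind advection in space and in
both state directions, central-difference diffusion, and the food sink.
Alongside the tendencies it accumulates, per cell, the total outflow
rate (1/hr); the integrator divides its CFL number by the maximum of
that array, which makes the forward-Euler update provably
positivity-preserving.

The same arithmetic is duplicated in plain numpy in
:mod:`hopperband.engine` as a slow reference path; the two are held
equal to round-off in the test suite.
"""

import numba
import numpy as np

__all__ = ["rhs_core", "periodic_tridiag_solve"]


@numba.njit(cache=False)
def _thomas(lo, di, up, rhs):
    """Standard tridiagonal solve (no wrap-around), overwrites nothing."""
    n = di.shape[0]
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = up[0] / di[0]
    dp[0] = rhs[0] / di[0]
    for i in range(1, n):
        m = di[i] - lo[i] * cp[i - 1]
        cp[i] = up[i] / m
        dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / m
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@numba.njit(cache=False)
def periodic_tridiag_solve(lo, di, up, rhs):
    """Solve a cyclic tridiagonal system by Sherman-Morrison.

    ``lo[i]`` couples unknown i to i-1, ``up[i]`` to i+1; ``lo[0]`` and
    ``up[n-1]`` are the periodic corner entries.
    """
    n = di.shape[0]
    a, b = lo[0], up[n - 1]
    gamma = -di[0]
    d2 = di.copy()
    d2[0] = di[0] - gamma
    d2[n - 1] = di[n - 1] - a * b / gamma
    y = _thomas(lo, d2, up, rhs)
    u = np.zeros(n)
    u[0] = gamma
    u[n - 1] = b
    z = _thomas(lo, d2, up, u)
    fact = (y[0] + a * y[n - 1] / gamma) / (1.0 + z[0] + a * z[n - 1] / gamma)
    return y - fact * z


@numba.njit(cache=False, fastmath=False)
def rhs_core(
    rho,        # (nx, G, H) density
    c,          # (nx,) food
    gQ,         # (nx,) face gradient of the social potential Q*rho_bar
    gT,         # (nx,) face gradient of rho_bar^2
    fc_face,    # (nx,) food mobility factor exp(-c) at faces
    dcf,        # (nx,) face gradient of c
    fn,         # (G,) signed social strength per ng cell
    flh,        # (H,) hunger mobility factor per nh cell
    psi,        # (H,) consumption factor per nh cell
    f_rel,      # (nx,) serotonin release rate f(rho_bar)
    ngf,        # (G-1,) interior ng faces
    nhf,        # (H-1,) interior nh faces
    D, gamma, k, eta_l, nu,
    dx, wg, wh,           # spatial cell size; state cell widths (1 if frozen)
    ng_active, nh_active,  # bools: advect that state axis?
    use_limiter,           # minmod-limited (second-order) spatial advection?
    drho, dc, rate,        # outputs: tendencies and per-cell outflow rate
):
    nx, G, H = rho.shape
    drho[:] = 0.0
    rate[:] = 0.0
    dvol = wg * wh

    # minmod-limited slopes along x (zero => donor-cell)
    slope = np.zeros((nx, G, H))
    if use_limiter:
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i + 1 < nx else 0
            for g in range(G):
                for h in range(H):
                    a = rho[i, g, h] - rho[im, g, h]
                    b = rho[ip, g, h] - rho[i, g, h]
                    if a * b > 0.0:
                        slope[i, g, h] = a if abs(a) < abs(b) else b

    # reconstructed face values can reach 1.5x the cell average, so the
    # positivity accounting doubles the advective outflow rate
    adv_safety = 2.0 if use_limiter else 1.0

    # --- spatial advection (upwind) + diffusion, flux at right faces ---
    for i in range(nx):
        ip = i + 1 if i + 1 < nx else 0
        gq = gQ[i]
        gt = gT[i]
        fcf = fc_face[i]
        dci = dcf[i]
        for h in range(H):
            fl_f = flh[h] * fcf
            # -fn*d(Q*rb) - D*[d(fl) + gamma*fl*d(rb^2)], d(fl) = -flh*e^-c*dc
            v_base = D * fl_f * dci - D * gamma * fl_f * gt
            dcoef = D * fl_f / dx
            for g in range(G):
                v = v_base - fn[g] * gq
                if v > 0.0:
                    flux = v * (rho[i, g, h] + 0.5 * slope[i, g, h])
                    rate[i, g, h] += adv_safety * v / dx
                else:
                    flux = v * (rho[ip, g, h] - 0.5 * slope[ip, g, h])
                    rate[ip, g, h] -= adv_safety * v / dx
                flux -= dcoef * (rho[ip, g, h] - rho[i, g, h])
                rate[i, g, h] += dcoef / dx
                rate[ip, g, h] += dcoef / dx
                drho[i, g, h] -= flux / dx
                drho[ip, g, h] += flux / dx

    # --- gregarisation advection, interior faces only (no-flux boundaries) ---
    if ng_active and G > 1:
        for i in range(nx):
            fr = f_rel[i]
            for j in range(G - 1):
                v = fr - k * ngf[j]
                for h in range(H):
                    if v > 0.0:
                        flux = v * rho[i, j, h]
                        rate[i, j, h] += v / wg
                    else:
                        flux = v * rho[i, j + 1, h]
                        rate[i, j + 1, h] -= v / wg
                    drho[i, j, h] -= flux / wg
                    drho[i, j + 1, h] += flux / wg

    # --- hunger advection, interior faces only ---
    if nh_active and H > 1:
        for i in range(nx):
            ci = c[i]
            for j in range(H - 1):
                v = eta_l * (2.0 - nhf[j]) * ci - nu * nhf[j]
                for g in range(G):
                    if v > 0.0:
                        flux = v * rho[i, g, j]
                        rate[i, g, j] += v / wh
                    else:
                        flux = v * rho[i, g, j + 1]
                        rate[i, g, j + 1] -= v / wh
                    drho[i, g, j] -= flux / wh
                    drho[i, g, j + 1] += flux / wh

    # --- food consumption ---
    for i in range(nx):
        s = 0.0
        for g in range(G):
            for h in range(H):
                s += psi[h] * rho[i, g, h]
        dc[i] = -c[i] * s * dvol

    mx = 0.0
    for i in range(nx):
        for g in range(G):
            for h in range(H):
                if rate[i, g, h] > mx:
                    mx = rate[i, g, h]
    return mx
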