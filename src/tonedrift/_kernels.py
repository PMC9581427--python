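"""Numba kernels: Crank-Nicolson first-passage solver and Euler path simulator.

The diffusion is dx = v dt + sigma dW (sigma = 1) between absorbing bounds at
+/-(B - t_B t) in bound-centred coordinates.  The solver propagates the
probability mass on a fixed spatial grid; mass at nodes overtaken by the
collapsing bound is handed to the nearer absorber, and the per-step absorbed
flux at each bound is computed from the same discrete operator used for the
interior update, so total probability is conserved to machine precision.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _thomas(sub, diag, sup, rhs, out, n):
    # standard tridiagonal solve; scratch arrays are reused by the caller
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = sup[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        m = diag[i] - sub[i] * cp[i - 1]
        cp[i] = sup[i] / m
        dp[i] = (rhs[i] - sub[i] * dp[i - 1]) / m
    out[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]


@njit(cache=True)
def solve_fpt_core(drift, B, t_B, x0, dt, dx_req, T):
    """Return (dens_upper, dens_lower, undecided) on the grid t = dt..n*dt.

    dens_* are defect decision-time densities (probability/second) for
    absorption at the upper (high-frequency) and lower bound.
    """
    n_steps = max(1, int(np.ceil(T / dt - 1e-9)))
    N = max(4, int(round(2.0 * B / dx_req)))
    dx = 2.0 * B / N
    D = 0.5  # sigma^2 / 2 with sigma = 1

    # mass per node, nodes k=0..N at x_k = -B + k dx; interior 1..N-1
    M = np.zeros(N + 1)
    xpos = x0 + B  # distance from lower bound in [0, 2B]
    k = int(xpos / dx)
    if k < 1:
        k = 1
    if k > N - 2:
        k = N - 2
    w = xpos / dx - k
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    M[k] = 1.0 - w
    M[k + 1] = w

    cu = D / dx ** 2 + drift / (2.0 * dx)   # transfer rate upward (to k+1)
    cd = D / dx ** 2 - drift / (2.0 * dx)   # transfer rate downward (to k-1)
    bdiag = -2.0 * D / dx ** 2

    dens_up = np.zeros(n_steps)
    dens_lo = np.zeros(n_steps)
    cur_lo, cur_hi = 1, N - 1

    sub = np.empty(N + 1)
    dia = np.empty(N + 1)
    sup = np.empty(N + 1)
    rhs = np.empty(N + 1)
    new = np.empty(N + 1)

    for step in range(n_steps):
        t_end = (step + 1) * dt
        h = B - t_B * t_end
        absorbed_up = 0.0
        absorbed_lo = 0.0

        if h <= dx * 0.5:
            # bound has (effectively) collapsed: force absorption by sign
            for kk in range(cur_lo, cur_hi + 1):
                x = -B + kk * dx
                if x > 1e-12:
                    absorbed_up += M[kk]
                elif x < -1e-12:
                    absorbed_lo += M[kk]
                else:
                    absorbed_up += 0.5 * M[kk]
                    absorbed_lo += 0.5 * M[kk]
                M[kk] = 0.0
            dens_up[step] = absorbed_up / dt
            dens_lo[step] = absorbed_lo / dt
            break

        # shrink the active window to the current bound; the cut is computed
        # once in grid cells and mirrored so the scheme stays exactly
        # symmetric under (drift, x0) -> (-drift, -x0)
        eaten = (B - h) / dx
        new_lo = int(np.floor(eaten + 1e-9)) + 1
        if new_lo < 1:
            new_lo = 1
        new_hi = N - new_lo
        for kk in range(cur_lo, min(new_lo, cur_hi + 1)):
            absorbed_lo += M[kk]
            M[kk] = 0.0
        for kk in range(max(new_hi + 1, cur_lo), cur_hi + 1):
            absorbed_up += M[kk]
            M[kk] = 0.0
        cur_lo, cur_hi = new_lo, new_hi
        if cur_lo > cur_hi:
            dens_up[step] = absorbed_up / dt
            dens_lo[step] = absorbed_lo / dt
            break

        n = cur_hi - cur_lo + 1
        # theta scheme: backward Euler for the first steps damps the
        # oscillations seeded by the delta initial condition (Rannacher
        # start-up), Crank-Nicolson afterwards.
        theta = 1.0 if step < 4 else 0.5
        for i in range(n):
            kk = cur_lo + i
            lo_nb = M[kk - 1] if kk - 1 >= cur_lo else 0.0
            hi_nb = M[kk + 1] if kk + 1 <= cur_hi else 0.0
            rhs[i] = M[kk] + (1.0 - theta) * dt * (
                cu * lo_nb + cd * hi_nb + bdiag * M[kk])
            sub[i] = -theta * dt * cu
            sup[i] = -theta * dt * cd
            dia[i] = 1.0 - theta * dt * bdiag
        _thomas(sub, dia, sup, rhs, new, n)

        # flux into the absorbers over this step (theta-weighted edge mass)
        absorbed_up += dt * cu * (theta * new[n - 1] + (1.0 - theta) * M[cur_hi])
        absorbed_lo += dt * cd * (theta * new[0] + (1.0 - theta) * M[cur_lo])
        for i in range(n):
            M[cur_lo + i] = new[i]

        # clamp the O(1e-10) negative flux the CN scheme can leak early on
        dens_up[step] = absorbed_up / dt if absorbed_up > 0.0 else 0.0
        dens_lo[step] = absorbed_lo / dt if absorbed_lo > 0.0 else 0.0

    undecided = 0.0
    for kk in range(N + 1):
        undecided += M[kk]
    return dens_up, dens_lo, undecided


@njit(cache=True)
def simulate_paths_core(drift, B, t_B, x0, T, dt_sim, n_paths, seed):
    """Euler-Maruyama paths; returns (choices, decision_times).

    choices: +1 upper bound, -1 lower bound, 0 undecided at T.
    """
    np.random.seed(seed)
    choices = np.zeros(n_paths, dtype=np.int8)
    times = np.full(n_paths, np.nan)
    sq = np.sqrt(dt_sim)
    # continuity correction for discretely monitored barriers
    # (Broadie-Glasserman): shrink the bound by 0.5826 sigma sqrt(dt)
    shrink = 0.5826 * sq
    n_steps = int(np.ceil(T / dt_sim))
    for p in range(n_paths):
        x = x0
        for s in range(1, n_steps + 1):
            x += drift * dt_sim + sq * np.random.normal()
            t = s * dt_sim
            h = B - t_B * t - shrink
            if h <= 0.0:
                if x > 0.0:
                    choices[p] = 1
                elif x < 0.0:
                    choices[p] = -1
                else:
                    choices[p] = 1 if np.random.random() < 0.5 else -1
                times[p] = t
                break
            if x >= h:
                choices[p] = 1
                times[p] = t
                break
            if x <= -h:
                choices[p] = -1
                times[p] = t
                break
    return choices, times


@njit(cache=True)
def simulate_trials_core(drifts, Bs, t_Bs, x0s, windows, ndts, dt_sim, seed):
    """One Euler path per trial with per-trial drivers.

    Returns (choices, rts): choice +1/-1/0 (0 = window expired before the
    bound was reached once non-decision time is added), rt in seconds.
    """
    np.random.seed(seed)
    n = drifts.shape[0]
    choices = np.zeros(n, dtype=np.int8)
    rts = np.full(n, np.nan)
    sq = np.sqrt(dt_sim)
    shrink = 0.5826 * sq  # discrete-barrier continuity correction
    for p in range(n):
        T = windows[p] - ndts[p]
        if T <= 0.0:
            continue
        n_steps = int(np.ceil(T / dt_sim))
        x = x0s[p]
        for s in range(1, n_steps + 1):
            x += drifts[p] * dt_sim + sq * np.random.normal()
            t = s * dt_sim
            h = Bs[p] - t_Bs[p] * t - shrink
            hit = 0
            if h <= 0.0:
                if x > 0.0:
                    hit = 1
                elif x < 0.0:
                    hit = -1
                else:
                    hit = 1 if np.random.random() < 0.5 else -1
            elif x >= h:
                hit = 1
            elif x <= -h:
                hit = -1
            if hit != 0:
                choices[p] = hit
                rts[p] = t + ndts[p]
                break
    return choices, rts


@njit(cache=True)
def solve_fpt_batch(drifts, x0s, B, t_B, dt, dx_req, T):
    """Batched first-passage solves sharing (B, t_B, dt, dx, T).

    Returns (dens_up, dens_lo, undecided) with one row per driver pair.
    """
    n_u = drifts.shape[0]
    n_steps = max(1, int(np.ceil(T / dt - 1e-9)))
    dens_up = np.zeros((n_u, n_steps))
    dens_lo = np.zeros((n_u, n_steps))
    und = np.zeros(n_u)
    for u in range(n_u):
        up, lo, m = solve_fpt_core(drifts[u], B, t_B, x0s[u], dt, dx_req, T)
        for j in range(up.shape[0]):
            dens_up[u, j] = up[j]
            dens_lo[u, j] = lo[j]
        und[u] = m
    return dens_up, dens_lo, und
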