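"""Numba-compiled inner loops: Metropolis MC (single and 3-PF) and Langevin.

These kernels are deliberately free of Python objects; the public modules
wrap them with dataclass configs and validation.  All randomness comes from
numba's per-thread NumPy RNG, seeded explicitly at kernel entry, so a given
(seed, config) pair reproduces trajectories bit-identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# single-chain Metropolis


@njit(cache=True)
def _lat_e(li, l0, lmax, ks, ems):
    if li < lmax:
        d = li - l0
        return 0.5 * ks * d * d
    return ems


@njit(cache=True)
def chain_mc(
    theta,          # (N,) initial bond angles; theta[0] = clamp, held fixed
    theta0,         # (N,) preferred bond angles
    b, l0, lmax, ks, kb, tfac,
    n_steps, burn_in, record_every, max_rot,
    bias_k, bias_c,  # harmonic umbrella bias 0.5*k*(Rx-c)^2 (k=0: unbiased)
    edges,          # histogram bin edges over Rx (uniform)
    seed,
):
    """Pivot-move Metropolis sampling of the chain.

    Returns (hist, trace_step, trace_rx, trace_e, n_accept, sum_rx, sum_rx2,
    n_meas, theta_final).  The histogram accumulates every post-burn-in step;
    the trace is thinned by ``record_every``.
    """
    np.random.seed(seed)
    N = theta.shape[0]
    theta = theta.copy()
    # cumulative orientations and node coordinates
    x = np.empty(N + 1)
    y = np.empty(N + 1)
    li = np.empty(N)
    x[0] = 0.0
    y[0] = 0.0
    cum = 0.0
    e_phys = 0.0
    ems = 0.5 * ks * (lmax - l0) ** 2
    for i in range(N):
        cum += theta[i]
        x[i + 1] = x[i] + b * np.cos(cum)
        y[i + 1] = y[i] + b * np.sin(cum)
        dx = x[i + 1] - b * (i + 1)
        dy = y[i + 1] + l0
        li[i] = np.sqrt(dx * dx + dy * dy)
        e_phys += _lat_e(li[i], l0, lmax, ks, ems)
        e_phys += kb * (1.0 - np.cos(theta[i] - theta0[i]))
    L = N * b
    rx = L - x[N]

    nb = edges.shape[0] - 1
    lo = edges[0]
    dxbin = edges[1] - edges[0]
    hist = np.zeros(nb, dtype=np.int64)
    n_rec = (n_steps - burn_in) // record_every + 1
    t_step = np.empty(n_rec, dtype=np.int64)
    t_rx = np.empty(n_rec)
    t_e = np.empty(n_rec)
    irec = 0

    xn = np.empty(N + 1)
    yn = np.empty(N + 1)
    lin = np.empty(N)

    n_accept = 0
    sum_rx = 0.0
    sum_rx2 = 0.0
    n_meas = 0

    for step in range(n_steps):
        j = 1 + np.int64(np.random.random() * (N - 1))
        if j >= N:
            j = N - 1
        dth = (np.random.random() * 2.0 - 1.0) * max_rot
        th_new = theta[j] + dth
        # rebuild downstream of node j
        de = kb * (
            np.cos(theta[j] - theta0[j]) - np.cos(th_new - theta0[j])
        )
        cum = 0.0
        for i in range(j):
            cum += theta[i]
        cum += th_new
        px = x[j]
        py = y[j]
        for k in range(j, N):
            if k > j:
                cum += theta[k]
            px = px + b * np.cos(cum)
            py = py + b * np.sin(cum)
            xn[k + 1] = px
            yn[k + 1] = py
            dx = px - b * (k + 1)
            dy = py + l0
            lnew = np.sqrt(dx * dx + dy * dy)
            lin[k] = lnew
            de += _lat_e(lnew, l0, lmax, ks, ems) - _lat_e(li[k], l0, lmax, ks, ems)
        rx_new = L - xn[N]
        dtot = de
        if bias_k > 0.0:
            dtot += 0.5 * bias_k * ((rx_new - bias_c) ** 2 - (rx - bias_c) ** 2)
        acc = False
        if dtot <= 0.0:
            acc = True
        elif tfac > 0.0 and np.random.random() < np.exp(-dtot / tfac):
            acc = True
        if acc:
            n_accept += 1
            theta[j] = th_new
            for k in range(j + 1, N + 1):
                x[k] = xn[k]
                y[k] = yn[k]
            for k in range(j, N):
                li[k] = lin[k]
            e_phys += de
            rx = rx_new
        if step >= burn_in:
            ib = np.int64((rx - lo) / dxbin)
            if 0 <= ib < nb:
                hist[ib] += 1
            sum_rx += rx
            sum_rx2 += rx * rx
            n_meas += 1
            if (step - burn_in) % record_every == 0 and irec < n_rec:
                t_step[irec] = step
                t_rx[irec] = rx
                t_e[irec] = e_phys
                irec += 1

    return (
        hist, t_step[:irec], t_rx[:irec], t_e[:irec],
        n_accept, sum_rx, sum_rx2, n_meas, theta,
    )


# ---------------------------------------------------------------------------
# three-protofilament Metropolis


@njit(cache=True)
def _pair_d(xa, ya, xb, yb, R):
    # 3-D distance between same-index nodes of adjacent PFs whose planes
    # meet the tube axis at 120 degrees; (x, y) are in-plane coordinates
    # with y the outward radial excursion and R the straight-state radius.
    ra = R + ya
    rb = R + yb
    dx = xa - xb
    return np.sqrt(dx * dx + ra * ra + rb * rb + ra * rb)


@njit(cache=True)
def mc3(
    theta,          # (3, N) bond angles per PF
    theta0,         # (N,) preferred angles (same composition on all PFs)
    bendable,       # (3,) uint8 mask
    b, l0, lmax, ks, kb, tfac,
    n_steps, burn_in, record_every, max_rot,
    edges, seed,
):
    """Metropolis sampling of three PFs on planes at 120 degrees.

    Lateral bond i of pair alpha connects node i of PF alpha with node i of
    PF alpha+1 (cyclic).  Only PFs flagged in ``bendable`` are moved; the
    others stay frozen straight.  Returns per-PF Rx histograms, per-PF
    running sums and the acceptance count.
    """
    np.random.seed(seed)
    N = theta.shape[1]
    theta = theta.copy()
    R = l0 / np.sqrt(3.0)
    ems = 0.5 * ks * (lmax - l0) ** 2

    x = np.empty((3, N + 1))
    y = np.empty((3, N + 1))
    for a in range(3):
        x[a, 0] = 0.0
        y[a, 0] = 0.0
        cum = 0.0
        for i in range(N):
            cum += theta[a, i]
            x[a, i + 1] = x[a, i] + b * np.cos(cum)
            y[a, i + 1] = y[a, i] + b * np.sin(cum)
    # lateral distances: pair a couples PF a and PF (a+1)%3
    lpair = np.empty((3, N))
    for a in range(3):
        a2 = (a + 1) % 3
        for i in range(N):
            lpair[a, i] = _pair_d(x[a, i + 1], y[a, i + 1], x[a2, i + 1], y[a2, i + 1], R)

    bend_idx = np.empty(3, dtype=np.int64)
    p = 0
    for a in range(3):
        if bendable[a]:
            bend_idx[p] = a
            p += 1

    L = N * b
    nb = edges.shape[0] - 1
    lo = edges[0]
    dxbin = edges[1] - edges[0]
    hist = np.zeros((3, nb), dtype=np.int64)
    sum_rx = np.zeros(3)
    sum_rx2 = np.zeros(3)
    n_meas = 0
    n_accept = 0

    xn = np.empty(N + 1)
    yn = np.empty(N + 1)
    lin1 = np.empty(N)   # pair (a, a+1)
    lin2 = np.empty(N)   # pair (a-1, a)

    for step in range(n_steps):
        a = bend_idx[np.int64(np.random.random() * p) % p]
        a_next = (a + 1) % 3
        a_prev = (a + 2) % 3
        j = 1 + np.int64(np.random.random() * (N - 1))
        if j >= N:
            j = N - 1
        dth = (np.random.random() * 2.0 - 1.0) * max_rot
        th_new = theta[a, j] + dth
        de = kb * (np.cos(theta[a, j] - theta0[j]) - np.cos(th_new - theta0[j]))
        cum = 0.0
        for i in range(j):
            cum += theta[a, i]
        cum += th_new
        px = x[a, j]
        py = y[a, j]
        for k in range(j, N):
            if k > j:
                cum += theta[a, k]
            px = px + b * np.cos(cum)
            py = py + b * np.sin(cum)
            xn[k + 1] = px
            yn[k + 1] = py
            l1 = _pair_d(px, py, x[a_next, k + 1], y[a_next, k + 1], R)
            l2 = _pair_d(x[a_prev, k + 1], y[a_prev, k + 1], px, py, R)
            lin1[k] = l1
            lin2[k] = l2
            de += _lat_e(l1, l0, lmax, ks, ems) - _lat_e(lpair[a, k], l0, lmax, ks, ems)
            de += _lat_e(l2, l0, lmax, ks, ems) - _lat_e(lpair[a_prev, k], l0, lmax, ks, ems)
        acc = False
        if de <= 0.0:
            acc = True
        elif tfac > 0.0 and np.random.random() < np.exp(-de / tfac):
            acc = True
        if acc:
            n_accept += 1
            theta[a, j] = th_new
            for k in range(j + 1, N + 1):
                x[a, k] = xn[k]
                y[a, k] = yn[k]
            for k in range(j, N):
                lpair[a, k] = lin1[k]
                lpair[a_prev, k] = lin2[k]
        if step >= burn_in and step % record_every == 0:
            n_meas += 1
            for a2 in range(3):
                rx = L - x[a2, N]
                sum_rx[a2] += rx
                sum_rx2[a2] += rx * rx
                ib = np.int64((rx - lo) / dxbin)
                if 0 <= ib < nb:
                    hist[a2, ib] += 1

    return hist, sum_rx, sum_rx2, n_meas, n_accept, theta, x, y


# ---------------------------------------------------------------------------
# overdamped Langevin on a tabulated landscape


@njit(cache=True)
def _interp(xq, x0, dx, tab):
    # linear interpolation on a uniform grid, clamped at the ends
    u = (xq - x0) / dx
    if u <= 0.0:
        return tab[0]
    n = tab.shape[0]
    if u >= n - 1:
        return tab[n - 1]
    i = np.int64(u)
    f = u - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True)
def langevin(
    grad,           # dF/dRx (kBT/nm) on a uniform grid
    x0, dx, xlo, xhi,
    D, dt, n_steps, record_every,
    rx_init, seed,
    k_off, rx_gate,     # dissociation: Poisson rate while Rx > rx_gate
    b, l_d, L0,
    lc_tab, rx0_tab,    # monotone Eq.-7 tables for the post-event remap
):
    """Euler-Maruyama tip dynamics with optional subunit dissociation.

    dRx = -D*F'(Rx)*dt + sqrt(2 D dt)*xi, reflecting at [xlo, xhi].
    While Rx > rx_gate, dissociation fires as a Poisson process with rate
    ``k_off``; each event removes one subunit (Nd += 1) and remaps Rx by
    shortening the peeled arc length by b through the zero-temperature
    tip-position relation (tables ``lc_tab``/``rx0_tab``).
    Records (t, Rx, Nd, Lobs) every ``record_every`` steps; stops early if
    the observable length reaches zero.
    """
    np.random.seed(seed)
    sq = np.sqrt(2.0 * D * dt)
    rx = rx_init
    nd = 0
    n_rec = n_steps // record_every + 1
    t_t = np.empty(n_rec)
    t_rx = np.empty(n_rec)
    t_nd = np.empty(n_rec, dtype=np.int64)
    t_lo = np.empty(n_rec)
    irec = 0
    p_off = k_off * dt
    stopped = False
    for step in range(n_steps):
        if step % record_every == 0 and irec < n_rec:
            t_t[irec] = step * dt
            t_rx[irec] = rx
            t_nd[irec] = nd
            t_lo[irec] = L0 - rx * l_d - b * nd
            irec += 1
            if t_lo[irec - 1] <= 0.0:
                stopped = True
                break
        f = _interp(rx, x0, dx, grad)
        rx = rx - D * f * dt + sq * np.random.normal()
        # mirror reflection at the support boundaries
        if rx < xlo:
            rx = 2.0 * xlo - rx
        if rx > xhi:
            rx = 2.0 * xhi - rx
        if rx < xlo:
            rx = xlo
        if p_off > 0.0 and rx > rx_gate and np.random.random() < p_off:
            nd += 1
            # current peeled length from Eq. 7 (leftmost inverse), minus b
            lc = np.interp(rx, rx0_tab, lc_tab)
            lc = lc - b
            if lc < 0.0:
                lc = 0.0
            rx = np.interp(lc, lc_tab, rx0_tab)
            if rx < xlo:
                rx = xlo
    if not stopped and irec < n_rec:
        t_t[irec] = n_steps * dt
        t_rx[irec] = rx
        t_nd[irec] = nd
        t_lo[irec] = L0 - rx * l_d - b * nd
        irec += 1
    return t_t[:irec], t_rx[:irec], t_nd[:irec], t_lo[:irec]


@njit(cache=True)
def first_passage(grad, x0, dx, xlo, B, D, dt, rx_init, seed, max_steps):
    """Time for the tip to first reach B, reflecting at xlo. NaN if not reached."""
    np.random.seed(seed)
    sq = np.sqrt(2.0 * D * dt)
    rx = rx_init
    for step in range(max_steps):
        f = _interp(rx, x0, dx, grad)
        rx = rx - D * f * dt + sq * np.random.normal()
        if rx < xlo:
            rx = 2.0 * xlo - rx
        if rx >= B:
            return (step + 1) * dt
    return np.nan
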