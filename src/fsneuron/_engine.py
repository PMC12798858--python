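"""Compiled integration kernel for the discretized cable model.

The cell is a single unbranched chain of nodes (dendrite tip ... dendrite,
soma, axon ... axon tip), so the voltage diffusion operator is tridiagonal.
Each time step advances gates with exponential Euler at the previous
voltage, then solves the voltage update implicitly (backward Euler) with
the channel conductances frozen at the new gate values — the standard
stable splitting for Hodgkin–Huxley cable models.

Channels live only on subsets of nodes; the kernel iterates precomputed
(channel, node) index lists rather than the full K x n product.

Gate parameter layout per channel (columns of ``act``/``inact``):
[v_half, v_slope, tau_max, tau_min, v_tau_half, v_tau_slope].
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel", "steady_gates", "channel_index_lists"]


def channel_index_lists(gbar, has_act, has_inact):
    """CSR-style (ptr, idx) node lists per channel for gating and currents."""

    def build(mask_rows):
        ptr = np.zeros(len(mask_rows) + 1, dtype=np.int64)
        idx_parts = []
        for k, row in enumerate(mask_rows):
            nodes = np.flatnonzero(row)
            idx_parts.append(nodes)
            ptr[k + 1] = ptr[k] + len(nodes)
        idx = (np.concatenate(idx_parts) if idx_parts
               else np.empty(0, dtype=np.int64)).astype(np.int64)
        return ptr, idx

    active = gbar > 0.0
    g_ptr, g_idx = build(list(active))
    a_ptr, a_idx = build([row if has_act[k] else np.zeros_like(row)
                          for k, row in enumerate(active)])
    h_ptr, h_idx = build([row if has_inact[k] else np.zeros_like(row)
                          for k, row in enumerate(active)])
    return g_ptr, g_idx, a_ptr, a_idx, h_ptr, h_idx


@njit(cache=True, fastmath=False)
def run_kernel(
    c,            # (n,) pF, per-node capacitance
    g_ax,         # (n-1,) nS, coupling conductance between node i and i+1
    soma,         # int, soma node index
    gbar,         # (K, n) nS, per-node total conductance per channel
    p_exp,        # (K,) int64 activation exponent
    e_rev,        # (K,) mV
    act,          # (K, 6) activation kinetics
    inact,        # (K, 6)
    has_inact,    # (K,) bool
    g_ptr, g_idx,  # current-sum index lists
    a_ptr, a_idx,  # activation-gate index lists
    h_ptr, h_idx,  # inactivation-gate index lists
    v,            # (n,) mV initial voltage, modified in place
    m,            # (K, n) gate state, modified in place
    h,            # (K, n)
    dt,           # ms
    i_stim,       # (T,) pA injected at soma
    g_syn,        # (T,) nS synaptic conductance at soma
    e_syn,        # mV
    rec_idx,      # (R,) int64 nodes to record
    clamp,        # bool: hold soma at v_clamp
    v_clamp,      # mV
    stop_margin,  # int64: if > 0, stop this many steps after the first
                  # recorded-node crossing of 0 mV (an unambiguous spike)
):
    """Advance T steps; returns (vrec (T, R), diverged_step or -1, n_done)."""
    n = c.shape[0]
    K = gbar.shape[0]
    T = i_stim.shape[0]
    R = rec_idx.shape[0]

    vrec = np.empty((T, R), dtype=np.float64)

    aa = np.empty(n, dtype=np.float64)   # sub-diagonal
    bb = np.empty(n, dtype=np.float64)   # diagonal
    cc = np.empty(n, dtype=np.float64)   # super-diagonal
    dd = np.empty(n, dtype=np.float64)   # rhs
    cp = np.empty(n, dtype=np.float64)
    dp = np.empty(n, dtype=np.float64)

    gtot = np.empty(n, dtype=np.float64)
    gdrv = np.empty(n, dtype=np.float64)  # sum of g_k * E_k

    diverged = -1
    stop_at = -1
    n_done = T

    for step in range(T):
        # --- gates: exponential Euler at current voltage -------------------
        for k in range(K):
            vh = act[k, 0]; vs = act[k, 1]
            tmax = act[k, 2]; tmin = act[k, 3]
            vth = act[k, 4]; vts = act[k, 5]
            for p in range(a_ptr[k], a_ptr[k + 1]):
                i = a_idx[p]
                xi = 0.5 + 0.5 * np.tanh((v[i] - vh) / vs)
                tb = np.tanh((v[i] - vth) / vts)
                tx = (tmax - tmin) * (1.0 - tb * tb) + tmin
                m[k, i] = xi + (m[k, i] - xi) * np.exp(-dt / tx)
            vh = inact[k, 0]; vs = inact[k, 1]
            tmax = inact[k, 2]; tmin = inact[k, 3]
            vth = inact[k, 4]; vts = inact[k, 5]
            for p in range(h_ptr[k], h_ptr[k + 1]):
                i = h_idx[p]
                xi = 0.5 + 0.5 * np.tanh((v[i] - vh) / vs)
                tb = np.tanh((v[i] - vth) / vts)
                tx = (tmax - tmin) * (1.0 - tb * tb) + tmin
                h[k, i] = xi + (h[k, i] - xi) * np.exp(-dt / tx)

        # --- membrane conductance / driving terms --------------------------
        for i in range(n):
            gtot[i] = 0.0
            gdrv[i] = 0.0
        for k in range(K):
            pk = p_exp[k]
            ek = e_rev[k]
            hk = has_inact[k]
            for p in range(g_ptr[k], g_ptr[k + 1]):
                i = g_idx[p]
                g = gbar[k, i]
                if pk > 0:
                    mp = m[k, i]
                    for _ in range(pk - 1):
                        mp *= m[k, i]
                    g = g * mp
                if hk:
                    g = g * h[k, i]
                gtot[i] += g
                gdrv[i] += g * ek

        gs = g_syn[step]
        if gs > 0.0:
            gtot[soma] += gs
            gdrv[soma] += gs * e_syn

        # --- implicit voltage update (tridiagonal solve) -------------------
        for i in range(n):
            bb[i] = c[i] / dt + gtot[i]
            dd[i] = (c[i] / dt) * v[i] + gdrv[i]
            aa[i] = 0.0
            cc[i] = 0.0
        dd[soma] += i_stim[step]
        for i in range(n - 1):
            g = g_ax[i]
            bb[i] += g
            bb[i + 1] += g
            cc[i] = -g
            aa[i + 1] = -g

        if clamp:
            aa[soma] = 0.0
            cc[soma] = 0.0
            bb[soma] = 1.0
            dd[soma] = v_clamp
            if soma > 0:
                dd[soma - 1] += g_ax[soma - 1] * v_clamp
                cc[soma - 1] = 0.0
            if soma < n - 1:
                dd[soma + 1] += g_ax[soma] * v_clamp
                aa[soma + 1] = 0.0

        # Thomas forward sweep
        cp[0] = cc[0] / bb[0]
        dp[0] = dd[0] / bb[0]
        for i in range(1, n):
            denom = bb[i] - aa[i] * cp[i - 1]
            cp[i] = cc[i] / denom
            dp[i] = (dd[i] - aa[i] * dp[i - 1]) / denom
        v[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]

        for r in range(R):
            vrec[step, r] = v[rec_idx[r]]

        if diverged < 0:
            for r in range(R):
                if not (-200.0 < vrec[step, r] < 200.0):
                    diverged = step
                    break
        if diverged >= 0:
            n_done = step + 1
            break
        if stop_margin > 0 and stop_at < 0:
            for r in range(R):
                if vrec[step, r] > 0.0:
                    stop_at = step + stop_margin
                    break
        if stop_at >= 0 and step >= stop_at:
            n_done = step + 1
            break

    return vrec, diverged, n_done


def steady_gates(v0, gbar, act, has_act, inact, has_inact):
    """Gate state arrays at steady state for a uniform voltage v0."""
    K, n = gbar.shape
    m = np.ones((K, n), dtype=np.float64)
    h = np.ones((K, n), dtype=np.float64)
    for k in range(K):
        if has_act[k]:
            m[k, :] = 0.5 + 0.5 * np.tanh((v0 - act[k, 0]) / act[k, 1])
        if has_inact[k]:
            h[k, :] = 0.5 + 0.5 * np.tanh((v0 - inact[k, 0]) / inact[k, 1])
    return m, h
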