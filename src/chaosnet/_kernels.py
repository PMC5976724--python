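"""Compiled inner loops: fixed-step Euler integration of HB + I_h networks
and the two-trajectory maximal-Lyapunov-exponent scheme.

Parameters arrive packed as an (N, 29) float64 matrix (see
``model.PARAM_COLUMNS``); connectivity as a CSR neighbour list
(indptr, indices) of the symmetric adjacency.  State is a (5, N) array
ordered (V, a_r, a_sd, a_sr, a_h).

Gap-junction coupling is diffusive: neuron k receives
I_syn,k = g * sum_l C_kl (V_l - V_k), which pulls V_k toward its
neighbours and sums to zero over the network for symmetric C.
"""

import numpy as np
from numba import njit

CA_HALF_SQ = 0.16  # 0.4^2 in the calcium Hill term
V_BLOWUP = 500.0   # |V| beyond this is a diverged run


@njit(cache=True, fastmath=False)
def _deriv_into(S, P, Isyn, out):
    N = S.shape[1]
    for n in range(N):
        V = S[0, n]
        a_r = S[1, n]
        a_sd = S[2, n]
        a_sr = S[3, n]
        a_h = S[4, n]
        C_m = P[n, 0]
        rho = P[n, 1]
        phi = P[n, 2]
        a_d = 1.0 / (1.0 + np.exp(-P[n, 13] * (V - P[n, 9])))
        I_d = rho * P[n, 3] * a_d * (V - P[n, 23])
        I_r = rho * P[n, 4] * a_r * (V - P[n, 24])
        I_sd = rho * P[n, 5] * a_sd * (V - P[n, 25])
        ca = a_sr * a_sr
        I_sr = rho * P[n, 6] * (ca / (ca + CA_HALF_SQ)) * (V - P[n, 26])
        I_l = rho * P[n, 7] * (V - P[n, 27])
        I_h = rho * P[n, 8] * a_h * (V - P[n, 28])
        out[0, n] = (-I_sd - I_sr - I_h - I_d - I_r - I_l + Isyn[n]) / C_m
        ar_inf = 1.0 / (1.0 + np.exp(-P[n, 14] * (V - P[n, 10])))
        asd_inf = 1.0 / (1.0 + np.exp(-P[n, 15] * (V - P[n, 11])))
        ah_inf = 1.0 / (1.0 + np.exp(-P[n, 16] * (V - P[n, 12])))
        out[1, n] = phi * (ar_inf - a_r) / P[n, 17]
        out[2, n] = phi * (asd_inf - a_sd) / P[n, 18]
        out[3, n] = phi * (-P[n, 21] * I_sd - P[n, 22] * a_sr) / P[n, 19]
        out[4, n] = phi * (ah_inf - a_h) / P[n, 20]


@njit(cache=True)
def _coupling_into(S, indptr, indices, g, Isyn):
    N = S.shape[1]
    for k in range(N):
        acc = 0.0
        vk = S[0, k]
        for e in range(indptr[k], indptr[k + 1]):
            acc += S[0, indices[e]] - vk
        Isyn[k] = g * acc


@njit(cache=True)
def euler_network(P, indptr, indices, g, S0, dt, n_transient, n_record,
                  stride, v_thresh, refr_steps, spike_cap):
    """Euler-integrate a coupled network.

    Returns (V_rec, spikes, spike_counts, S_final, blew_up_at).  V_rec is
    sampled every ``stride`` steps during the recording phase (including
    step 0 of it); spike times (ms, relative to recording start, linearly
    interpolated threshold crossings) are detected at full resolution.
    ``blew_up_at`` is the global step index of divergence, or -1.
    """
    N = S0.shape[1]
    S = S0.copy()
    D = np.empty((5, N))
    Isyn = np.zeros(N)
    n_rec_samples = n_record // stride + 1
    V_rec = np.empty((N, n_rec_samples))
    spikes = np.zeros((N, spike_cap))
    counts = np.zeros(N, dtype=np.int64)
    last_spike_step = np.full(N, -refr_steps - 1, dtype=np.int64)
    total = n_transient + n_record
    rec_i = 0
    for step in range(total + 1):
        if step >= n_transient:
            r = step - n_transient
            if r % stride == 0 and rec_i < n_rec_samples:
                for n in range(N):
                    V_rec[n, rec_i] = S[0, n]
                rec_i += 1
        if step == total:
            break
        _coupling_into(S, indptr, indices, g, Isyn)
        _deriv_into(S, P, Isyn, D)
        for n in range(N):
            vold = S[0, n]
            vnew = vold + dt * D[0, n]
            S[0, n] = vnew
            S[1, n] += dt * D[1, n]
            S[2, n] += dt * D[2, n]
            S[3, n] += dt * D[3, n]
            S[4, n] += dt * D[4, n]
            if not np.isfinite(vnew) or vnew > V_BLOWUP or vnew < -V_BLOWUP:
                return V_rec, spikes, counts, S, step
            if step >= n_transient and vold < v_thresh <= vnew:
                if step - last_spike_step[n] > refr_steps:
                    last_spike_step[n] = step
                    if counts[n] < spike_cap:
                        frac = (v_thresh - vold) / (vnew - vold)
                        t_ms = (step - n_transient + frac) * dt
                        spikes[n, counts[n]] = t_ms
                        counts[n] += 1
    return V_rec, spikes, counts, S, -1


@njit(cache=True)
def _advance(S, D, P, indptr, indices, g, Isyn, dt, n_steps):
    """In-place Euler advance; returns False on blow-up."""
    N = S.shape[1]
    for _ in range(n_steps):
        _coupling_into(S, indptr, indices, g, Isyn)
        _deriv_into(S, P, Isyn, D)
        for n in range(N):
            for v in range(5):
                S[v, n] += dt * D[v, n]
        v0 = S[0, 0]
        if not np.isfinite(v0) or v0 > V_BLOWUP or v0 < -V_BLOWUP:
            return False
    return True


@njit(cache=True)
def mle_network(P, indptr, indices, g, S0, dt, n_transient, renorm_steps,
                n_renorms, d0, seed):
    """Two-trajectory MLE: evolve a reference and a copy displaced by d0
    (Euclidean norm over the raw state vector), rescale the separation
    back to d0 every ``renorm_steps`` steps, and collect log(d_i/d0).

    Returns (logs, ok): per-interval log stretch factors and a success
    flag (False on trajectory divergence).
    """
    np.random.seed(seed)
    N = S0.shape[1]
    S1 = S0.copy()
    D = np.empty((5, N))
    Isyn = np.zeros(N)
    if not _advance(S1, D, P, indptr, indices, g, Isyn, dt, n_transient):
        return np.zeros(0), False
    pert = np.random.standard_normal((5, N))
    pert /= np.sqrt(np.sum(pert * pert))
    S2 = S1 + d0 * pert
    logs = np.empty(n_renorms)
    for i in range(n_renorms):
        if not _advance(S1, D, P, indptr, indices, g, Isyn, dt, renorm_steps):
            return logs[:i], False
        if not _advance(S2, D, P, indptr, indices, g, Isyn, dt, renorm_steps):
            return logs[:i], False
        d = 0.0
        for n in range(N):
            for v in range(5):
                dd = S2[v, n] - S1[v, n]
                d += dd * dd
        d = np.sqrt(d)
        if d == 0.0:
            pert = np.random.standard_normal((5, N))
            pert /= np.sqrt(np.sum(pert * pert))
            S2 = S1 + d0 * pert
            logs[i] = 0.0
            continue
        logs[i] = np.log(d / d0)
        f = d0 / d
        for n in range(N):
            for v in range(5):
                S2[v, n] = S1[v, n] + (S2[v, n] - S1[v, n]) * f
    return logs, True
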