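"""Numba-compiled inner loops for the spiking engine.

The kernels duplicate, for speed, the dynamics defined readably in
:mod:`rstdp.lif` (membrane/conductance update) and :mod:`rstdp.spiking`
(pairwise STDP, outcome classification); the test-suite pins the two paths
together.  Everything is written against plain arrays and scalars so that
numba can compile it; the dataclass-level API lives in
:mod:`rstdp.spiking`.

Outcome label codes: 0 converged, 1 extreme_weights, 2 weights_too_similar,
3 did_not_converge.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Deeply hyperpolarized membranes (total conductance below -1 makes the
# Euler update exponentially divergent) are saturated here instead of
# aborting: the excursion is transient and recovers once the conductance
# decays, mirroring how bounded state variables absorb pathological drive.
_V_FLOOR = -1e6


@njit(cache=True, fastmath=True)
def _presentation(W, Q, j_bar, j_bar_h, env, tau_m, v_rest, v_thresh, v_reset,
                  g_gain, tau_syn, d, noise_mean, sig_noise, sig_input,
                  tau_stdp, Lsp, Hsp, pp, poT, rng):
    """One stimulus presentation; fills rasters and STDP pair sums in place.

    ``pp[i, k]`` accumulates exp-windowed joint activity for pairs where the
    higher (pre-synaptic) neuron ``k`` fired before the lower (post) neuron
    ``i``; ``poT[k, i]`` the reverse ordering.  Simultaneous spikes (lag 0)
    contribute to neither side.  Returns (n_lower_spikes, pathological).
    """
    nL, nH = W.shape
    T = env.shape[0]
    dec_syn = np.exp(-1.0 / tau_syn)
    dec_stdp = np.exp(-1.0 / tau_stdp)
    VL = np.full(nL, v_rest)
    VH = np.full(nH, v_rest)
    gL = np.zeros(nL)
    gH = np.zeros(nH)
    xL = np.zeros(nL)
    xH = np.zeros(nH)
    tdrive = np.zeros(nL)
    bdrive = np.zeros(nH)
    Lsp[:] = 0
    Hsp[:] = 0
    pp[:] = 0.0
    poT[:] = 0.0
    n_sp_lower = 0
    higher_ext = j_bar_h.shape[0] > 0
    for t in range(T):
        td = t - d
        for i in range(nL):
            tdrive[i] = 0.0
        for k in range(nH):
            bdrive[k] = 0.0
        if td >= 0:
            for k in range(nH):
                if Hsp[k, td] == 1:
                    for i in range(nL):
                        tdrive[i] += W[i, k]
            for i in range(nL):
                if Lsp[i, td] == 1:
                    for k in range(nH):
                        bdrive[k] += Q[k, i]
        for i in range(nL):
            rate = j_bar[i] * env[t]
            j = 0.0
            if rate > 0.0:
                j = rng.normal(rate, sig_input * rate)
                if j < 0.0:
                    j = 0.0
            noise = rng.normal(noise_mean, sig_noise * noise_mean)
            if noise < 0.0:
                noise = 0.0
            gL[i] = gL[i] * dec_syn + g_gain * ((j + noise) * 0.001 + tdrive[i])
            VL[i] += (1.0 / tau_m) * ((v_rest - VL[i]) - gL[i] * VL[i])
            if VL[i] < _V_FLOOR:
                VL[i] = _V_FLOOR
        for k in range(nH):
            ext = 0.0
            if higher_ext:
                rate_h = j_bar_h[k] * env[t]
                if rate_h > 0.0:
                    ext = rng.normal(rate_h, sig_input * rate_h)
                    if ext < 0.0:
                        ext = 0.0
            noise = rng.normal(noise_mean, sig_noise * noise_mean)
            if noise < 0.0:
                noise = 0.0
            gH[k] = gH[k] * dec_syn + g_gain * ((ext + noise) * 0.001 + bdrive[k])
            VH[k] += (1.0 / tau_m) * ((v_rest - VH[k]) - gH[k] * VH[k])
            if VH[k] < _V_FLOOR:
                VH[k] = _V_FLOOR
        # spike emission + pairing with the pre-t filtered traces, so that
        # simultaneous (lag-0) spikes never pair
        for i in range(nL):
            if VL[i] >= v_thresh:
                Lsp[i, t] = 1
                VL[i] = v_reset
                gL[i] = 0.0
                n_sp_lower += 1
                for k in range(nH):
                    pp[i, k] += xH[k]
        for k in range(nH):
            if VH[k] >= v_thresh:
                Hsp[k, t] = 1
                VH[k] = v_reset
                gH[k] = 0.0
                for i in range(nL):
                    poT[k, i] += xL[i]
        for i in range(nL):
            xL[i] = dec_stdp * (xL[i] + Lsp[i, t])
        for k in range(nH):
            xH[k] = dec_stdp * (xH[k] + Hsp[k, t])
    return n_sp_lower, False


@njit(cache=True, fastmath=True)
def _pearson_flat(A, B):
    n = A.size
    ma = A.mean()
    mb = B.mean()
    num = 0.0
    va = 0.0
    vb = 0.0
    for idx in range(n):
        a = A.flat[idx] - ma
        b = B.flat[idx] - mb
        num += a * b
        va += a * a
        vb += b * b
    if va <= 0.0 or vb <= 0.0:
        return 0.0
    return num / np.sqrt(va * vb)


@njit(cache=True, fastmath=True)
def train_spiking_kernel(
    W, Q, Csq, Csq_h, env,
    # stimulus
    j_mean, j_rel, sig_input, higher_ratio,
    # membrane / synapse
    tau_m, v_rest, v_thresh, v_reset, g_gain, tau_syn, d, noise_mean, sig_noise,
    # learning rule
    tau_stdp, a_plus, alpha, reverse, w_max,
    # stopping criteria
    max_pres, stride, corr_lag, std_lag, ext_margin, ext_frac,
    corr_thresh, std_change_frac, div_thresh,
    # homeostasis (eta_eff <= 0 disables)
    homeo_eta_eff, homeo_F, homeo_interval, input_gain,
    # multiplicative soft bounds
    multiplicative,
    # concurrent bottom-up plasticity (conc_rate <= 0 disables)
    conc_rate, conc_alpha, conc_reverse,
    # weight snapshots at the requested presentation counts
    snapshot_at, snapshots,
    # per-stride diagnostics: N, std_W, corr_lagged, rate_lower, frac_extreme
    diag,
    rng,
):
    """Full training loop; returns (label_code, n_stop, pathological, n_diag)."""
    nL, nH = W.shape
    T = env.shape[0]
    Lsp = np.zeros((nL, T), np.uint8)
    Hsp = np.zeros((nH, T), np.uint8)
    pp = np.zeros((nL, nH))
    poT = np.zeros((nH, nL))
    n_ring = std_lag // stride + 1
    ring = np.zeros((n_ring, nL, nH))
    ring_N = np.full(n_ring, -1, np.int64)
    presentation_s = T * 0.001
    homeo_counts = np.zeros(nL)
    label = 3
    n_stop = max_pres
    pathological = False
    n_diag = 0
    n_snap = 0
    for N in range(1, max_pres + 1):
        # correlated per-presentation input strengths, rectified at zero
        z = np.empty(nL)
        for i in range(nL):
            z[i] = rng.normal(0.0, 1.0)
        j_bar = j_mean + j_rel * j_mean * (Csq @ z)
        for i in range(nL):
            if j_bar[i] < 0.0:
                j_bar[i] = 0.0
        if higher_ratio > 0.0:
            zh = np.empty(nH)
            for k in range(nH):
                zh[k] = rng.normal(0.0, 1.0)
            j_bar_h = higher_ratio * (j_mean + j_rel * j_mean * (Csq_h @ zh))
            for k in range(nH):
                if j_bar_h[k] < 0.0:
                    j_bar_h[k] = 0.0
        else:
            j_bar_h = np.empty(0)
        for i in range(nL):
            j_bar[i] *= input_gain[i]

        n_sp, patho = _presentation(
            W, Q, j_bar, j_bar_h, env, tau_m, v_rest, v_thresh, v_reset,
            g_gain, tau_syn, d, noise_mean, sig_noise, sig_input,
            tau_stdp, Lsp, Hsp, pp, poT, rng)
        if patho:
            label = 1
            n_stop = N
            pathological = True
            break

        # apply the accumulated STDP update, then clip to the hard bounds
        for i in range(nL):
            for k in range(nH):
                pot = poT[k, i] if reverse else pp[i, k]
                dep = pp[i, k] if reverse else poT[k, i]
                if multiplicative:
                    # soft bounds, normalized so the factors are order one
                    w = W[i, k]
                    dw = a_plus * ((w_max - w) / w_max * pot
                                   - alpha * np.abs(w) / w_max * dep)
                else:
                    dw = a_plus * (pot - alpha * dep)
                w = W[i, k] + dw
                if w > w_max:
                    w = w_max
                elif w < -w_max:
                    w = -w_max
                W[i, k] = w
        if conc_rate > 0.0:
            for k in range(nH):
                for i in range(nL):
                    # bottom-up synapse: lower is pre-synaptic, higher post
                    pot_q = poT[k, i] if not conc_reverse else pp[i, k]
                    dep_q = pp[i, k] if not conc_reverse else poT[k, i]
                    q = Q[k, i] + conc_rate * (pot_q - conc_alpha * dep_q)
                    if q > w_max:
                        q = w_max
                    elif q < -w_max:
                        q = -w_max
                    Q[k, i] = q

        if homeo_eta_eff > 0.0:
            for i in range(nL):
                cnt = 0.0
                for t in range(T):
                    cnt += Lsp[i, t]
                homeo_counts[i] += cnt
            if N % homeo_interval == 0:
                for i in range(nL):
                    r = homeo_counts[i] / (homeo_interval * presentation_s)
                    f = 1.0 + homeo_eta_eff * (homeo_F - r) / homeo_F
                    if f < 0.5:
                        f = 0.5
                    elif f > 2.0:
                        f = 2.0
                    for k in range(nH):
                        w = W[i, k] * f
                        if w > w_max:
                            w = w_max
                        elif w < -w_max:
                            w = -w_max
                        W[i, k] = w
                    input_gain[i] *= f
                    homeo_counts[i] = 0.0

        if n_snap < snapshot_at.shape[0] and N == snapshot_at[n_snap]:
            snapshots[n_snap] = W
            n_snap += 1

        if N % stride == 0:
            n_ext = 0
            for i in range(nL):
                for k in range(nH):
                    if np.abs(np.abs(W[i, k]) - w_max) < ext_margin:
                        n_ext += 1
            frac_ext = n_ext / (nL * nH)
            corr = np.nan
            s_now = W.std()
            slot_c = ((N - corr_lag) // stride) % n_ring
            slot_s = ((N - std_lag) // stride) % n_ring
            if ring_N[slot_c] == N - corr_lag:
                corr = _pearson_flat(W, ring[slot_c])
            diag[n_diag, 0] = N
            diag[n_diag, 1] = s_now
            diag[n_diag, 2] = corr
            diag[n_diag, 3] = n_sp / nL / presentation_s
            diag[n_diag, 4] = frac_ext
            n_diag += 1
            if frac_ext > ext_frac:
                label = 1
                n_stop = N
                break
            if ring_N[slot_c] == N - corr_lag and ring_N[slot_s] == N - std_lag:
                s_then = ring[slot_s].std()
                if (s_now > 0.0 and corr > corr_thresh
                        and np.abs(s_now - s_then) < std_change_frac * s_now):
                    label = 0 if s_now > div_thresh else 2
                    n_stop = N
                    break
                # degenerate spread: the lagged correlation of a collapsed
                # weight distribution is noise-dominated and cannot certify
                # stability, so stability is read from the mean magnitude
                if s_now < div_thresh:
                    m_now = np.abs(W).mean()
                    m_then = np.abs(ring[slot_s]).mean()
                    if np.abs(m_now - m_then) <= std_change_frac * m_now + 1e-12:
                        label = 2
                        n_stop = N
                        break
            slot = (N // stride) % n_ring
            ring[slot] = W
            ring_N[slot] = N
    return label, n_stop, pathological, n_diag
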