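"""Conductance-based leaky integrate-and-fire dynamics.

Each neuron follows

    tau_m dV/dt = (V_rest - V) + g (E_exc - V),        E_exc = 0 mV

integrated by forward Euler on a 1 ms grid.  The excitatory conductance
``g`` (dimensionless) accumulates increments of ``g_gain`` per incoming
spike-equivalent, decays exponentially with ``tau_syn``, and is cleared
whenever the neuron itself fires — it tracks only inputs received since the
neuron's last action potential.  Crossing ``v_thresh`` emits a spike and
resets the membrane to ``v_reset``.

Lower-layer neurons receive the external stimulus drive, excitatory noise
spikes and delayed top-down spikes through ``W``; higher-layer neurons
receive delayed bottom-up spikes through ``Q``, noise and (optionally) their
own external drive.  Weights are signed; a negative weight contributes
negatively to ``g`` and thereby hyperpolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LIFConfig", "integrate_membrane", "run_presentation_reference"]


@dataclass(frozen=True)
class LIFConfig:
    """Membrane, synapse and noise constants for the spiking engine."""

    tau_m: float = 10.0          # ms
    v_rest: float = -74.0        # mV
    e_exc: float = 0.0           # mV
    v_thresh: float = -54.0      # mV
    v_reset: float = -60.0       # mV
    g_gain: float = 0.04         # conductance increment per spike
    tau_syn_ms: float = 15.0     # ms
    delay_ms: int = 15           # inter-layer transmission delay, ms
    noise_mean: float = 2000.0   # spikes/s of excitatory noise
    sigma_noise: float = 1.0     # noise s.d. as a fraction of the mean
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_thresh:
            raise ValueError("v_reset must lie below v_thresh")
        if min(self.tau_m, self.tau_syn_ms, self.dt_ms) <= 0:
            raise ValueError("time constants must be positive")
        if self.delay_ms % self.dt_ms != 0:
            raise ValueError("dt must divide the transmission delay")
        if self.delay_ms < self.dt_ms:
            raise ValueError("delay must be at least one time step")
        if self.noise_mean < 0 or self.sigma_noise < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay_ms / self.dt_ms))


def integrate_membrane(
    g_trace: np.ndarray,
    lif: LIFConfig,
    v0: float | None = None,
    reset_g_on_spike: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Reference integrator for a single neuron with a prescribed conductance.

    Returns the membrane trace (value *after* each step, with reset applied)
    and the spike-time indices.  When ``reset_g_on_spike`` is set the
    remaining conductance trace is zeroed at each spike, mirroring the
    network dynamics; with it off, ``g_trace`` acts as a clamp, which is the
    configuration with simple closed-form behaviour used in tests.
    """
    g = np.asarray(g_trace, dtype=float).copy()
    v = lif.v_rest if v0 is None else float(v0)
    out = np.empty(len(g))
    spikes: list[int] = []
    scale = lif.dt_ms / lif.tau_m
    for t in range(len(g)):
        v += scale * ((lif.v_rest - v) + g[t] * (lif.e_exc - v))
        if v >= lif.v_thresh:
            spikes.append(t)
            v = lif.v_reset
            if reset_g_on_spike:
                g[t + 1:] = 0.0
        out[t] = v
    return out, spikes


def run_presentation_reference(
    W: np.ndarray,
    Q: np.ndarray,
    lif: LIFConfig,
    j_bar: np.ndarray,
    env: np.ndarray,
    sigma_input: float,
    rng: np.random.Generator,
    j_bar_higher: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pure-numpy implementation of one stimulus presentation.

    Slow but transparent; the numba kernel in :mod:`rstdp._kernels` is the
    production path and is held to agree with this reference in tests.
    Returns boolean spike rasters ``(lower, higher)`` of shape ``(n, T)``.
    """
    nL, nH = W.shape
    T = len(env)
    d = lif.delay_steps
    VL = np.full(nL, lif.v_rest)
    VH = np.full(nH, lif.v_rest)
    gL = np.zeros(nL)
    gH = np.zeros(nH)
    Lsp = np.zeros((nL, T), dtype=bool)
    Hsp = np.zeros((nH, T), dtype=bool)
    dec = np.exp(-lif.dt_ms / lif.tau_syn_ms)
    dt_s = lif.dt_ms / 1000.0
    scale = lif.dt_ms / lif.tau_m
    for t in range(T):
        td = t - d
        top_down = W @ Hsp[:, td] if td >= 0 else np.zeros(nL)
        bottom_up = Q @ Lsp[:, td] if td >= 0 else np.zeros(nH)
        rate = j_bar * env[t]
        j = np.clip(rng.normal(rate, sigma_input * rate), 0.0, None)
        noiseL = np.clip(rng.normal(lif.noise_mean, lif.sigma_noise * lif.noise_mean, nL), 0.0, None)
        noiseH = np.clip(rng.normal(lif.noise_mean, lif.sigma_noise * lif.noise_mean, nH), 0.0, None)
        ext_h = np.zeros(nH)
        if j_bar_higher is not None:
            rate_h = j_bar_higher * env[t]
            ext_h = np.clip(rng.normal(rate_h, sigma_input * rate_h), 0.0, None)
        gL = gL * dec + lif.g_gain * ((j + noiseL) * dt_s + top_down)
        gH = gH * dec + lif.g_gain * ((ext_h + noiseH) * dt_s + bottom_up)
        VL += scale * ((lif.v_rest - VL) + gL * (lif.e_exc - VL))
        VH += scale * ((lif.v_rest - VH) + gH * (lif.e_exc - VH))
        # deep hyperpolarization saturates instead of diverging
        np.clip(VL, -1e6, None, out=VL)
        np.clip(VH, -1e6, None, out=VH)
        fireL = VL >= lif.v_thresh
        fireH = VH >= lif.v_thresh
        Lsp[fireL, t] = True
        Hsp[fireH, t] = True
        VL[fireL] = lif.v_reset
        VH[fireH] = lif.v_reset
        gL[fireL] = 0.0
        gH[fireH] = 0.0
    return Lsp, Hsp
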