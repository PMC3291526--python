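"""Spiking engine: training of top-down weights in the LIF network.

One training run is a long sequence of 160 ms stimulus presentations.  For
each presentation a correlated input-strength vector is drawn, the network
of noisy conductance-based integrate-and-fire neurons is integrated at
1 ms resolution (:mod:`rstdp.lif`), and the top-down weights are updated by
an exponential-window pairwise STDP rule applied to every spike pair of the
presentation:

    |dw| = A_plus * exp(-|lag| / tau_stdp)        potentiating side
    |dw| = alpha * A_plus * exp(-|lag| / tau_stdp)  depressing side

Classical STDP potentiates pre-before-post pairs (higher-layer neurons are
pre-synaptic at a top-down synapse); reverse STDP potentiates
post-before-pre pairs.  Updates accumulate over the presentation, are
applied at its end, and the weights are clipped to ``[-w_max, +w_max]``.

Runs are classified with the four-way scheme of
:class:`rstdp.records.OutcomeRecord` using lagged weight correlations and
the spread of the final weight distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import train_spiking_kernel
from .lif import LIFConfig
from .records import (CONVERGED, DID_NOT_CONVERGE, EXTREME_WEIGHTS,
                      WEIGHTS_TOO_SIMILAR, OutcomeRecord)
from .stimulus import Envelope, StimulusEnsemble, input_time_course

__all__ = [
    "SpikingRuleSpec",
    "SpikingStopCriteria",
    "SpikePresentationRecord",
    "run_presentation_spiking",
    "stdp_pair_sums_spiking",
    "stdp_weight_update",
    "classify_spiking",
    "train_spiking",
    "initial_top_down_spiking",
]

_LABEL_CODES = dict(enumerate([CONVERGED, EXTREME_WEIGHTS,
                               WEIGHTS_TOO_SIMILAR, DID_NOT_CONVERGE]))


@dataclass(frozen=True)
class SpikingRuleSpec:
    """Pairwise STDP rule for the spiking engine."""

    orientation: str = "reverse"
    alpha: float = 1.2
    a_plus: float = 0.01
    tau_stdp_ms: float = 20.0
    w_max: float = 50.0

    def __post_init__(self) -> None:
        if self.orientation not in ("classical", "reverse"):
            raise ValueError("orientation must be 'classical' or 'reverse'")
        if self.alpha <= 0 or self.a_plus <= 0 or self.tau_stdp_ms <= 0:
            raise ValueError("alpha, a_plus and tau_stdp must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")

    @property
    def depression_biased(self) -> bool:
        return self.alpha > 1.0


@dataclass(frozen=True)
class SpikingStopCriteria:
    """Stopping rules for spiking training.

    A run stops as ``extreme_weights`` when more than ``extreme_fraction``
    of the weights sit within ``extreme_margin`` of the bounds.  It stops as
    stabilized when the correlation with the weights ``corr_lag``
    presentations earlier exceeds ``corr_thresh`` *and* the weight spread
    changed by less than ``std_change_fraction`` (relative) over the
    previous ``std_lag`` presentations; a stabilized run is ``converged``
    when the spread exceeds ``diversity_std_thresh`` and
    ``weights_too_similar`` otherwise.  Reaching ``max_presentations``
    without stabilizing is ``did_not_converge``.
    """

    extreme_fraction: float = 0.50
    extreme_margin: float = 0.1
    corr_lag: int = 3000
    corr_thresh: float = 0.99
    std_lag: int = 6000
    std_change_fraction: float = 0.001
    diversity_std_thresh: float = 0.3
    max_presentations: int = 625_000
    stride: int = 100

    def __post_init__(self) -> None:
        if min(self.extreme_fraction, self.extreme_margin, self.corr_lag,
               self.corr_thresh, self.std_lag, self.std_change_fraction,
               self.diversity_std_thresh, self.max_presentations, self.stride) <= 0:
            raise ValueError("all criteria must be positive")
        if not self.corr_lag < self.std_lag <= self.max_presentations:
            raise ValueError("need corr_lag < std_lag <= max_presentations")
        if self.corr_lag % self.stride or self.std_lag % self.stride:
            raise ValueError("stride must divide the correlation lags")


@dataclass(frozen=True)
class SpikePresentationRecord:
    """Spike rasters from one presentation (entries 0/1, shape ``(n, T)``)."""

    lower_spikes: np.ndarray
    higher_spikes: np.ndarray
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        L = np.asarray(self.lower_spikes)
        H = np.asarray(self.higher_spikes)
        if L.ndim != 2 or H.ndim != 2 or L.shape[1] != H.shape[1]:
            raise ValueError("rasters must be (n, T) with matching T")
        object.__setattr__(self, "lower_spikes", L.astype(np.uint8))
        object.__setattr__(self, "higher_spikes", H.astype(np.uint8))

    @property
    def duration_s(self) -> float:
        return self.lower_spikes.shape[1] * self.dt_ms / 1000.0

    def mean_rates(self) -> tuple[float, float]:
        """Mean firing rate (spikes/s) per layer."""
        return (float(self.lower_spikes.mean(axis=1).mean() / (self.dt_ms / 1000.0)),
                float(self.higher_spikes.mean(axis=1).mean() / (self.dt_ms / 1000.0)))

    def spike_times(self, layer: str = "lower") -> list[np.ndarray]:
        raster = self.lower_spikes if layer == "lower" else self.higher_spikes
        return [np.nonzero(row)[0] * self.dt_ms for row in raster]


def _envelope_grid(env: Envelope, dt_ms: float) -> np.ndarray:
    t = np.arange(0.0, env.presentation_ms, dt_ms)
    return np.asarray(input_time_course(t, env), dtype=float)


def run_presentation_spiking(
    W: np.ndarray,
    Q: np.ndarray,
    lif: LIFConfig,
    ensemble: StimulusEnsemble,
    j_bar: np.ndarray,
    rng: np.random.Generator,
    j_bar_higher: np.ndarray | None = None,
) -> SpikePresentationRecord:
    """Integrate one stimulus presentation and return the spike rasters."""
    from ._kernels import _presentation

    W = np.ascontiguousarray(W, dtype=float)
    Q = np.ascontiguousarray(Q, dtype=float)
    nL, nH = W.shape
    env = _envelope_grid(ensemble.envelope, lif.dt_ms)
    T = len(env)
    Lsp = np.zeros((nL, T), np.uint8)
    Hsp = np.zeros((nH, T), np.uint8)
    pp = np.zeros((nL, nH))
    poT = np.zeros((nH, nL))
    jh = np.empty(0) if j_bar_higher is None else np.asarray(j_bar_higher, float)
    _, patho = _presentation(
        W, Q, np.asarray(j_bar, float), jh, env,
        lif.tau_m, lif.v_rest, lif.v_thresh, lif.v_reset, lif.g_gain,
        lif.tau_syn_ms, lif.delay_steps, lif.noise_mean, lif.sigma_noise,
        ensemble.sigma_input, 20.0, Lsp, Hsp, pp, poT, rng)
    if patho:
        raise FloatingPointError("membrane potential diverged during presentation")
    return SpikePresentationRecord(Lsp, Hsp, lif.dt_ms)


def stdp_pair_sums_spiking(
    record: SpikePresentationRecord, tau_stdp_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially windowed pair sums over all spike pairs.

    Returns ``(pre_post, post_pre)``: ``pre_post[i, k]`` sums
    ``exp(-lag/tau)`` over pairs where higher neuron ``k`` (pre-synaptic)
    fired before lower neuron ``i``; ``post_pre`` the reverse order.  Lag-0
    pairs contribute to neither.  Implemented with causal exponential
    filters, equivalent to the explicit double loop over spike pairs.
    """
    L = record.lower_spikes.astype(float)
    H = record.higher_spikes.astype(float)
    T = L.shape[1]
    dec = np.exp(-record.dt_ms / tau_stdp_ms)
    XL = np.zeros_like(L)
    XH = np.zeros_like(H)
    for t in range(1, T):
        XL[:, t] = dec * (XL[:, t - 1] + L[:, t - 1])
        XH[:, t] = dec * (XH[:, t - 1] + H[:, t - 1])
    pre_post = L @ XH.T
    post_pre = XL @ H.T
    return pre_post, post_pre


def stdp_weight_update(
    rule: SpikingRuleSpec, record: SpikePresentationRecord, W: np.ndarray
) -> np.ndarray:
    """Apply one presentation's accumulated STDP update and clip."""
    pre_post, post_pre = stdp_pair_sums_spiking(record, rule.tau_stdp_ms)
    if rule.orientation == "classical":
        dW = rule.a_plus * (pre_post - rule.alpha * post_pre)
    else:
        dW = rule.a_plus * (post_pre - rule.alpha * pre_post)
    return np.clip(W + dW, -rule.w_max, rule.w_max)


def classify_spiking(
    weight_history: dict[int, np.ndarray] | "pd.Series",
    criteria: SpikingStopCriteria | None = None,
    w_max: float = 50.0,
) -> OutcomeRecord:
    """Classify a run from weight snapshots taken every ``stride``.

    ``weight_history`` maps presentation count to the weight matrix at that
    point.  Snapshots are scanned in order; the first stopping rule to fire
    determines the outcome.  Lagged rules only become active once snapshots
    ``corr_lag`` and ``std_lag`` presentations back exist.
    """
    crit = criteria or SpikingStopCriteria()
    items = sorted(weight_history.items())
    hist = dict(items)
    for N, W in items:
        W = np.asarray(W, float)
        frac_ext = np.mean(np.abs(np.abs(W) - w_max) < crit.extreme_margin)
        if frac_ext > crit.extreme_fraction:
            return OutcomeRecord(EXTREME_WEIGHTS, N,
                                 {"frac_extreme": float(frac_ext)})
        prev_c = hist.get(N - crit.corr_lag)
        prev_s = hist.get(N - crit.std_lag)
        if prev_c is not None and prev_s is not None:
            corr = _pearson(W, prev_c)
            s_now = float(W.std())
            s_then = float(np.asarray(prev_s, float).std())
            if (corr > crit.corr_thresh and s_now > 0
                    and abs(s_now - s_then) < crit.std_change_fraction * s_now):
                label = CONVERGED if s_now > crit.diversity_std_thresh else WEIGHTS_TOO_SIMILAR
                return OutcomeRecord(label, N, {"corr_lagged": corr,
                                                "final_std": s_now})
            if s_now < crit.diversity_std_thresh:
                # collapsed distribution: lagged correlation is noise-
                # dominated, so stability is read from the mean magnitude
                m_now = float(np.abs(W).mean())
                m_then = float(np.abs(np.asarray(prev_s, float)).mean())
                if abs(m_now - m_then) <= crit.std_change_fraction * m_now + 1e-12:
                    return OutcomeRecord(WEIGHTS_TOO_SIMILAR, N,
                                         {"final_std": s_now})
    N_last, W_last = items[-1]
    return OutcomeRecord(DID_NOT_CONVERGE, N_last,
                         {"final_std": float(np.asarray(W_last).std())})


def _pearson(A, B) -> float:
    a = np.asarray(A, float).ravel()
    b = np.asarray(B, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def initial_top_down_spiking(
    n_lower: int, n_higher: int, rng: np.random.Generator,
    scale: float = 0.05,
) -> np.ndarray:
    """Uniform initial top-down weights in ``[-scale, +scale]``."""
    return rng.uniform(-scale, scale, (n_lower, n_higher))


def train_spiking(
    Q: np.ndarray,
    ensemble: StimulusEnsemble,
    rule: SpikingRuleSpec,
    lif: LIFConfig | None = None,
    criteria: SpikingStopCriteria | None = None,
    rng: np.random.Generator | int | None = None,
    W0: np.ndarray | None = None,
    homeostasis=None,
    multiplicative: bool = False,
    concurrent=None,
    higher_input=None,
    snapshot_at: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, OutcomeRecord, pd.DataFrame, dict[int, np.ndarray]]:
    """Run a complete spiking training experiment.

    Returns ``(W_final, outcome, trace, snapshots)`` where ``trace`` has one
    row per ``stride`` presentations with columns ``N``, ``std_W``,
    ``corr_lagged``, ``rate_lower`` and ``frac_extreme``, and ``snapshots``
    maps each requested presentation count to a copy of ``W``.

    Optional mechanism blocks (:mod:`rstdp.variants`): ``homeostasis``
    rescales each lower neuron's input gain toward a target rate,
    ``multiplicative`` switches to the soft-bound weight-dependent rule,
    ``concurrent`` co-trains the bottom-up weights, and ``higher_input``
    adds an external stimulus ensemble for the higher layer.
    """
    lif = lif or LIFConfig()
    crit = criteria or SpikingStopCriteria()
    rng = np.random.default_rng(rng)
    Q = np.ascontiguousarray(Q, dtype=float).copy()
    nH, nL = Q.shape
    if W0 is None:
        W = initial_top_down_spiking(nL, nH, rng)
    else:
        W = np.ascontiguousarray(W0, dtype=float).copy()
    env = _envelope_grid(ensemble.envelope, lif.dt_ms)

    homeo_eta_eff, homeo_F, homeo_interval = 0.0, 1.0, 30
    if homeostasis is not None:
        homeo_eta_eff = homeostasis.eta_eff
        homeo_F = homeostasis.target_rate
        homeo_interval = homeostasis.interval
    conc_rate, conc_alpha, conc_reverse = 0.0, 1.0, False
    if concurrent is not None:
        conc_rate = abs(concurrent.zeta) * rule.a_plus
        conc_alpha = concurrent.alpha_q
        conc_reverse = concurrent.orientation_q == "reverse"
    higher_ratio = 0.0
    Csq_h = np.empty((0, 0))
    if higher_input is not None and higher_input.strength_ratio > 0:
        higher_ratio = higher_input.strength_ratio
        Csq_h = higher_input.C_sqrt(nH, rng)

    snap_at = np.asarray(sorted(snapshot_at or []), dtype=np.int64)
    snaps_arr = np.zeros((len(snap_at), nL, nH))
    n_diag_max = crit.max_presentations // crit.stride + 1
    diag = np.full((n_diag_max, 5), np.nan)
    input_gain = np.ones(nL)

    code, n_stop, patho, n_diag = train_spiking_kernel(
        W, Q, ensemble.C_sqrt, Csq_h, env,
        ensemble.j_mean, ensemble.rel_spread, ensemble.sigma_input, higher_ratio,
        lif.tau_m, lif.v_rest, lif.v_thresh, lif.v_reset, lif.g_gain,
        lif.tau_syn_ms, lif.delay_steps, lif.noise_mean, lif.sigma_noise,
        rule.tau_stdp_ms, rule.a_plus, rule.alpha,
        rule.orientation == "reverse", rule.w_max,
        crit.max_presentations, crit.stride, crit.corr_lag, crit.std_lag,
        crit.extreme_margin, crit.extreme_fraction, crit.corr_thresh,
        crit.std_change_fraction, crit.diversity_std_thresh,
        homeo_eta_eff, homeo_F, homeo_interval, input_gain,
        multiplicative,
        conc_rate, conc_alpha, conc_reverse,
        snap_at, snaps_arr, diag, rng)

    trace = pd.DataFrame(diag[:n_diag],
                         columns=["N", "std_W", "corr_lagged", "rate_lower",
                                  "frac_extreme"])
    outcome = OutcomeRecord(_LABEL_CODES[code], int(n_stop), {
        "final_std": float(W.std()),
        "frac_extreme": float(np.mean(np.abs(np.abs(W) - rule.w_max)
                                      < crit.extreme_margin)),
        "pathological": bool(patho),
        "mean_rate_lower": float(np.nanmean(trace["rate_lower"])) if n_diag else None,
    })
    snapshots = {int(N): snaps_arr[i] for i, N in enumerate(snap_at)
                 if N <= n_stop}
    return W, outcome, trace, snapshots
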