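"""Linear rate-model engine.

Neurons are linear: activity at each time point is the weighted sum of
activity at the previous one.  A stimulus presentation starts with external
input ``x`` in the lower layer, propagates up through ``Q`` and back down
through ``W``, alternating layers at successive (abstract) time points:

    L(1) = x,  H(2) = Q L(1),  L(3) = W H(2),  H(4) = Q L(3), ...

After each presentation the top-down weights change according to a
pair-based timing rule applied to all adjacent time-point pairs.  Writing
``post_pre`` for the summed joint activity of lower-before-higher pairs and
``pre_post`` for higher-before-lower pairs (the higher layer is always
pre-synaptic for a top-down synapse):

    classical STDP:  dW = mu * (pre_post - alpha * post_pre)
    reverse STDP:    dW = mu * (post_pre - alpha * pre_post)

``alpha`` weights the depressing side in both orientations; ``alpha > 1``
means depression dominates.  In ``expected`` mode the update is evaluated in
closed form against the stimulus cross-correlation ``C = E[x x^T]`` instead
of sampling stimuli, which removes sampling noise and makes training
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import NetworkMatrices, loop_gain_spectrum
from .records import (CONVERGED, DID_NOT_CONVERGE, EXTREME_WEIGHTS,
                      WEIGHTS_TOO_SIMILAR, OutcomeRecord)

__all__ = [
    "LinearRuleSpec",
    "LinearStimulus",
    "ActivityTrajectory",
    "LinearStopCriteria",
    "simulate_presentation_linear",
    "stdp_pair_sums",
    "stdp_delta_linear",
    "expected_pair_sums",
    "expected_stdp_delta",
    "predicted_fixed_point",
    "train_linear",
    "classify_linear",
]

ORIENTATIONS = ("classical", "reverse")
UPDATE_MODES = ("expected", "per_stimulus")


@dataclass(frozen=True)
class LinearRuleSpec:
    """Timing rule for the linear engine.

    orientation:
        ``"classical"`` potentiates higher-before-lower (pre-before-post)
        joint activity; ``"reverse"`` potentiates lower-before-higher.
    alpha:
        Depression-to-potentiation ratio; ``alpha > 1`` is depression-biased.
    mu:
        Learning rate per presentation.
    update_mode:
        ``"expected"`` uses the stimulus correlation matrix directly;
        ``"per_stimulus"`` draws an input vector for every presentation.
    """

    orientation: str = "reverse"
    alpha: float = 3.0
    mu: float = 2.5e-4
    update_mode: str = "expected"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.update_mode not in UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {UPDATE_MODES}")

    @property
    def depression_biased(self) -> bool:
        return self.alpha > 1.0


@dataclass(frozen=True)
class LinearStimulus:
    """Zero-mean Gaussian stimulus ensemble with cross-correlation ``C``."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("C must be symmetric")
        evals = np.linalg.eigvalsh(C)
        if evals.min() < -1e-8:
            raise ValueError("C must be positive semidefinite")
        object.__setattr__(self, "C", C)
        evals_c = np.clip(evals, 0.0, None)
        evecs = np.linalg.eigh(C)[1]
        object.__setattr__(self, "_C_sqrt", (evecs * np.sqrt(evals_c)) @ evecs.T)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self._C_sqrt @ rng.standard_normal(self.n)  # type: ignore[attr-defined]


@dataclass(frozen=True)
class ActivityTrajectory:
    """Layer activities over one presentation.

    ``L_series[k]`` is lower-layer activity at time point ``2k + 1`` and
    ``H_series[k]`` is higher-layer activity at time point ``2k + 2``; the
    layers strictly alternate.  ``finite`` is False when the loop gain blew
    the activity up to non-finite values (the caller treats this as a strong
    loop rather than an error).
    """

    L_series: np.ndarray  # (n_L_points, n_lower)
    H_series: np.ndarray  # (n_H_points, n_higher)
    finite: bool = True

    def __post_init__(self) -> None:
        L = np.atleast_2d(np.asarray(self.L_series, dtype=float))
        H = np.atleast_2d(np.asarray(self.H_series, dtype=float))
        if not L.shape[0] - 1 <= H.shape[0] <= L.shape[0]:
            raise ValueError("layers must strictly alternate starting from L")
        object.__setattr__(self, "L_series", L)
        object.__setattr__(self, "H_series", H)

    @property
    def n_timepoints(self) -> int:
        return self.L_series.shape[0] + self.H_series.shape[0]


def simulate_presentation_linear(
    net: NetworkMatrices, x: np.ndarray, T: int = 9
) -> ActivityTrajectory:
    """Propagate external input ``x`` up and down for ``T`` time points.

    The top-down weights are held fixed within the presentation (plasticity
    is slow compared to activity).  Non-finite activity (runaway loop gain)
    is flagged on the returned trajectory instead of raising.
    """
    if T < 3:
        raise ValueError("T must be at least 3")
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_lower,):
        raise ValueError(f"x must have length {net.n_lower}")
    L = [x]
    H = []
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(2, T + 1):
            if t % 2 == 0:
                H.append(net.Q @ L[-1])
            else:
                L.append(net.W @ H[-1])
    L_arr, H_arr = np.array(L), np.array(H)
    finite = bool(np.isfinite(L_arr).all() and np.isfinite(H_arr).all())
    return ActivityTrajectory(L_arr, H_arr, finite=finite)


def stdp_pair_sums(trajectory: ActivityTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Joint-activity sums over all adjacent time-point pairs.

    Returns ``(post_pre, pre_post)`` where ``post_pre[i, j]`` sums
    ``L_i(t) * H_j(t + 1)`` over pairs with the lower (post-synaptic) unit
    active first, and ``pre_post[i, j]`` sums ``L_i(t + 1) * H_j(t)`` over
    pairs with the higher (pre-synaptic) unit active first.
    """
    L, H = trajectory.L_series, trajectory.H_series
    n_pp = H.shape[0]               # pairs (L(2k+1), H(2k+2))
    n_prp = L.shape[0] - 1          # pairs (H(2k+2), L(2k+3))
    post_pre = L[:n_pp].T @ H[:n_pp]
    pre_post = L[1:1 + n_prp].T @ H[:n_prp]
    return post_pre, pre_post


def _apply_rule(
    rule: LinearRuleSpec, post_pre: np.ndarray, pre_post: np.ndarray
) -> np.ndarray:
    if rule.orientation == "classical":
        return rule.mu * (pre_post - rule.alpha * post_pre)
    return rule.mu * (post_pre - rule.alpha * pre_post)


def stdp_delta_linear(
    rule: LinearRuleSpec, trajectory: ActivityTrajectory
) -> np.ndarray:
    """Weight change from one presentation's activity trajectory."""
    post_pre, pre_post = stdp_pair_sums(trajectory)
    return _apply_rule(rule, post_pre, pre_post)


def expected_pair_sums(
    W: np.ndarray, Q: np.ndarray, C: np.ndarray, T: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Expectation of :func:`stdp_pair_sums` over the stimulus ensemble.

    With ``M = W Q`` the lower-layer activity at time ``2k + 1`` is
    ``M^k x``, so the expected lower-layer second moment there is
    ``S_k = M^k C M^k^T`` and

        E[post_pre] = sum_k S_k Q^T        (lower at 2k+1, higher at 2k+2)
        E[pre_post] = sum_k M S_k Q^T      (lower at 2k+3, higher at 2k+2)
    """
    if T < 3:
        raise ValueError("T must be at least 3")
    M = W @ Q
    n_pp = (T - 1) // 2
    n_prp = (T - 1) // 2 if T % 2 else T // 2 - 1
    post_pre = np.zeros_like(W)
    pre_post = np.zeros_like(W)
    S = np.asarray(C, dtype=float)
    for k in range(max(n_pp, n_prp)):
        if k < n_pp:
            post_pre += S @ Q.T
        if k < n_prp:
            pre_post += M @ S @ Q.T
        S = M @ S @ M.T
    return post_pre, pre_post


def expected_stdp_delta(
    rule: LinearRuleSpec,
    W: np.ndarray,
    Q: np.ndarray,
    C: np.ndarray,
    T: int = 9,
) -> np.ndarray:
    """Expected weight change per presentation (deterministic update)."""
    post_pre, pre_post = expected_pair_sums(W, Q, C, T)
    return _apply_rule(rule, post_pre, pre_post)


def predicted_fixed_point(Q: np.ndarray, rule: LinearRuleSpec) -> np.ndarray:
    """Top-down weights at which the expected weight change vanishes.

    For invertible ``Q`` the fixed point is a scaled inverse,
    ``W* = c Q^{-1}``: the loop gain ``W* Q = c I`` must have all eigenvalues
    equal to ``1/alpha`` under the reverse rule and ``alpha`` under the
    classical rule, so ``c = 1/alpha`` respectively ``alpha``.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != Q.shape[1]:
        raise np.linalg.LinAlgError("fixed point requires a square, invertible Q")
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"Q is singular to working precision (condition number {cond:.3g})"
        )
    c = 1.0 / rule.alpha if rule.orientation == "reverse" else rule.alpha
    return c * np.linalg.inv(Q)


@dataclass(frozen=True)
class LinearStopCriteria:
    """Stopping rules for linear training, checked in priority order.

    1. Any loop-gain eigenvalue above ``eigen_limit`` in modulus stops the
       run as ``extreme_weights``.
    2. Weight spread below ``similarity_fraction`` of its initial value
       stops it as ``weights_too_similar``.
    3. Over the trailing ``window`` presentations, if the fitted slopes of
       both the weight spread and the update norm are below
       ``slope_fraction`` of their window means, and the mean update norm is
       below ``small_change_rel`` times the weight norm, the run converged.
    4. Otherwise the run stops at ``max_iterations`` as ``did_not_converge``.
    """

    eigen_limit: float = 1.0
    similarity_fraction: float = 0.10
    window: int = 50
    slope_fraction: float = 0.001
    small_change_rel: float = 1e-6
    max_iterations: int = 20_000

    def __post_init__(self) -> None:
        if min(self.eigen_limit, self.similarity_fraction, self.window,
               self.slope_fraction, self.small_change_rel, self.max_iterations) <= 0:
            raise ValueError("all stopping thresholds must be positive")


def _slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=float)
    x -= x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def _check_stop(
    n: int,
    std_w: np.ndarray,
    dw_norm: np.ndarray,
    max_eig: np.ndarray,
    w_norm: float,
    std_initial: float,
    crit: LinearStopCriteria,
) -> str | None:
    """Evaluate the stopping rules at presentation ``n`` (1-based).

    Arrays hold per-presentation diagnostics up to and including ``n``.
    Priority: pathological outcomes are checked before convergence so that a
    run that is simultaneously flat and degenerate is never reported as a
    success.
    """
    i = n - 1
    if max_eig[i] > crit.eigen_limit:
        return EXTREME_WEIGHTS
    if std_initial > 0 and std_w[i] < crit.similarity_fraction * std_initial:
        return WEIGHTS_TOO_SIMILAR
    if n >= crit.window:
        ws = std_w[n - crit.window:n]
        wd = dw_norm[n - crit.window:n]
        flat_std = abs(_slope(ws)) < crit.slope_fraction * abs(ws.mean())
        small = wd.mean() < crit.small_change_rel * w_norm
        # a vanishing update norm counts as "constant in magnitude" even
        # while it still decays exponentially
        flat_dw = (abs(_slope(wd)) < crit.slope_fraction * abs(wd.mean())
                   or small)
        moved = dw_norm[:n].sum() > 0
        if flat_std and flat_dw and small and moved:
            return CONVERGED
    if n >= crit.max_iterations:
        return DID_NOT_CONVERGE
    return None


def classify_linear(trace: pd.DataFrame, criteria: LinearStopCriteria | None = None) -> OutcomeRecord:
    """Classify a recorded diagnostics trace under the four-way scheme.

    ``trace`` needs columns ``std_W``, ``dw_norm`` and ``max_eig_mod``
    indexed per presentation; the initial weight spread is taken from the
    ``std_W_initial`` attribute if present, else the first row.
    """
    crit = criteria or LinearStopCriteria()
    std_w = trace["std_W"].to_numpy(dtype=float)
    dw_norm = trace["dw_norm"].to_numpy(dtype=float)
    max_eig = trace["max_eig_mod"].to_numpy(dtype=float)
    w_norm = trace["w_norm"].to_numpy(dtype=float) if "w_norm" in trace else np.ones_like(std_w)
    std_initial = float(trace.attrs.get("std_W_initial", std_w[0]))
    for n in range(1, len(std_w) + 1):
        label = _check_stop(n, std_w, dw_norm, max_eig, float(w_norm[n - 1]),
                            std_initial, crit)
        if label is not None:
            return OutcomeRecord(label, n, {"final_std": float(std_w[n - 1]),
                                            "max_eig_mod": float(max_eig[n - 1])})
    return OutcomeRecord(
        DID_NOT_CONVERGE, len(std_w),
        {"final_std": float(std_w[-1]), "max_eig_mod": float(max_eig[-1])})


def initial_top_down(
    n_lower: int, n_higher: int, scale: float = 1e-3,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random normally distributed initial top-down weights.

    The scale is kept small so that the initial loop gain is far below one:
    training then probes whether the learning rule itself keeps the loop
    weak, rather than starting from an already-pathological circuit.
    """
    rng = np.random.default_rng(rng)
    return scale * rng.standard_normal((n_lower, n_higher))


def train_linear(
    net: NetworkMatrices,
    stimulus: LinearStimulus,
    rule: LinearRuleSpec,
    criteria: LinearStopCriteria | None = None,
    rng: np.random.Generator | int | None = None,
    T: int = 9,
    corr_lag: int = 100,
    multiplicative=None,
    concurrent=None,
    homeostasis=None,
) -> tuple[NetworkMatrices, OutcomeRecord, pd.DataFrame]:
    """Iterate stimulus presentations until a stopping rule fires.

    Returns the final network, the outcome record and a per-presentation
    diagnostics trace (update norm, weight spread, loop-gain modulus,
    lag-``corr_lag`` weight correlation, and correlation with the predicted
    fixed point when ``Q`` is square).

    The optional ``multiplicative``, ``concurrent`` and ``homeostasis``
    arguments take the parameter blocks from :mod:`rstdp.variants` and
    modify the update accordingly.
    """
    from . import variants as _variants

    crit = criteria or LinearStopCriteria()
    rng = np.random.default_rng(rng)
    W = net.W.copy()
    Q = net.Q.copy()
    C0 = stimulus.C
    std_initial = float(W.std())
    w_fp = None
    if Q.shape[0] == Q.shape[1]:
        try:
            w_fp = predicted_fixed_point(Q, rule)
        except np.linalg.LinAlgError:
            w_fp = None

    cap = crit.max_iterations
    std_w = np.empty(cap)
    dw_norm = np.empty(cap)
    max_eig = np.empty(cap)
    corr_lagged = np.full(cap, np.nan)
    corr_fp = np.full(cap, np.nan)
    ring = np.empty((corr_lag + 1,) + W.shape)
    input_gain = np.ones(net.n_lower)
    rate_window: list[np.ndarray] = []

    label = DID_NOT_CONVERGE
    n = 0
    lin_stim = stimulus
    for n in range(1, cap + 1):
        C_eff = C0 if homeostasis is None else (input_gain[:, None] * C0) * input_gain[None, :]
        if rule.update_mode == "expected":
            post_pre, pre_post = expected_pair_sums(W, Q, C_eff, T)
            if homeostasis is not None:
                rate_window.append(_expected_rates(W, Q, C_eff, T))
        else:
            if homeostasis is not None and n > 1:
                lin_stim = LinearStimulus((input_gain[:, None] * C0) * input_gain[None, :])
            x = lin_stim.draw(rng)
            traj = simulate_presentation_linear(
                NetworkMatrices(Q, W), x, T)
            if not traj.finite:
                post_pre = pre_post = None
            else:
                post_pre, pre_post = stdp_pair_sums(traj)
                if homeostasis is not None:
                    rate_window.append(np.abs(traj.L_series).mean(axis=0))

        if post_pre is None:
            # Activity overflowed within the presentation: strong loop.
            std_w[n - 1] = W.std()
            dw_norm[n - 1] = np.inf
            max_eig[n - 1] = np.inf
            label = EXTREME_WEIGHTS
            break

        if multiplicative is not None:
            pot, dep = _variants.multiplicative_stdp_factors(W, multiplicative.w_max)
            if rule.orientation == "classical":
                dW = rule.mu * (pot * pre_post - rule.alpha * dep * post_pre)
            else:
                dW = rule.mu * (pot * post_pre - rule.alpha * dep * pre_post)
        else:
            dW = _apply_rule(rule, post_pre, pre_post)
        W = W + dW
        if concurrent is not None:
            Q = Q + _variants.concurrent_bottom_up_delta_linear(
                rule, concurrent, post_pre, pre_post)
        if homeostasis is not None and n % homeostasis.interval == 0:
            rates = np.mean(rate_window, axis=0)
            rate_window.clear()
            W, input_gain = _variants.homeostatic_rescale(
                W, input_gain, rates, homeostasis)

        ring[n % (corr_lag + 1)] = W
        std_w[n - 1] = W.std()
        dw_norm[n - 1] = np.linalg.norm(dW)
        with np.errstate(over="ignore", invalid="ignore"):
            eig = loop_gain_spectrum(Q, W)
        max_eig[n - 1] = float(np.abs(eig).max()) if np.isfinite(eig).all() else np.inf
        if n > corr_lag:
            prev = ring[(n - corr_lag) % (corr_lag + 1)]
            corr_lagged[n - 1] = _pearson(W, prev)
        if w_fp is not None:
            corr_fp[n - 1] = _pearson(W, w_fp)

        stop = _check_stop(n, std_w, dw_norm, max_eig, float(np.linalg.norm(W)),
                           std_initial, crit)
        if stop is not None:
            label = stop
            break

    trace = pd.DataFrame({
        "N": np.arange(1, n + 1),
        "dw_norm": dw_norm[:n],
        "std_W": std_w[:n],
        "max_eig_mod": max_eig[:n],
        "corr_lagged": corr_lagged[:n],
        "corr_fixed_point": corr_fp[:n],
    })
    trace.attrs["std_W_initial"] = std_initial
    diagnostics = {
        "final_std": float(std_w[n - 1]),
        "max_eig_mod": float(max_eig[n - 1]),
        "max_eig_mod_run": float(np.nanmax(max_eig[:n])),
        "corr_fixed_point": float(corr_fp[n - 1]) if w_fp is not None else None,
        "dw_norm_final": float(dw_norm[n - 1]),
    }
    final = NetworkMatrices(Q, W)
    return final, OutcomeRecord(label, n, diagnostics), trace


def _pearson(A: np.ndarray, B: np.ndarray) -> float:
    a = A.ravel() - A.mean()
    b = B.ravel() - B.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _expected_rates(W: np.ndarray, Q: np.ndarray, C: np.ndarray, T: int) -> np.ndarray:
    """RMS lower-layer activity per neuron, averaged over time points."""
    M = W @ Q
    S = np.asarray(C, dtype=float)
    n_pts = (T + 1) // 2
    acc = np.zeros(W.shape[0])
    for _ in range(n_pts):
        acc += np.diag(S)
        S = M @ S @ M.T
    return np.sqrt(acc / n_pts)
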