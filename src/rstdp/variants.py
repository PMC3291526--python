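"""Modified plasticity rules: homeostasis, soft bounds, concurrent learning.

These mechanisms are stabilizers known to tame runaway Hebbian learning in
feedforward settings; the package implements them for both engines so the
central question — does anything other than depression-biased reverse STDP
yield stable, diverse, weak top-down weights — can be re-asked with each
mechanism switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import build_input_correlation, correlation_sqrt

__all__ = [
    "HomeostasisParams",
    "MultiplicativeParams",
    "ConcurrentParams",
    "HigherInputParams",
    "homeostatic_rescale",
    "multiplicative_stdp_factors",
    "concurrent_bottom_up_delta_linear",
]

# Base homeostatic step per interval at relative strength 1.  The grid's
# relative strengths (0.1 ... 100) multiply this; the clip below keeps even
# the strongest setting from overshooting in a single application.
_HOMEO_BASE_RATE = 0.01
_HOMEO_CLIP = (0.5, 2.0)


@dataclass(frozen=True)
class HomeostasisParams:
    """Multiplicative synaptic scaling toward a target firing rate.

    Every ``interval`` presentations each lower neuron's top-down row and
    external-input gain are multiplied by a factor that is 1 at the target
    rate ``target_rate`` (spikes/s) and moves the rate toward it otherwise.
    ``strength`` is the relative learning rate (dimensionless).
    """

    target_rate: float = 80.0
    strength: float = 1.0
    interval: int = 30

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        if self.interval < 1:
            raise ValueError("interval must be at least 1")

    @property
    def eta_eff(self) -> float:
        return self.strength * _HOMEO_BASE_RATE


@dataclass(frozen=True)
class MultiplicativeParams:
    """Soft-bound (weight-dependent) STDP.

    Potentiation scales with the distance of the weight from ``w_max``,
    depression with its distance from zero; weights then have two attracting
    values per synapse (near 0 and near ``w_max``), which is what destroys
    diversity under this rule.
    """

    w_max: float = 50.0

    def __post_init__(self) -> None:
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


@dataclass(frozen=True)
class ConcurrentParams:
    """Concurrent plasticity of the bottom-up weights.

    ``zeta`` is the bottom-up learning rate relative to the top-down one; a
    negative ``zeta`` selects the reverse orientation for the bottom-up rule
    (the explicit ``orientation_q`` keyword overrides the sign convention).
    ``alpha_q`` is the bottom-up depression/potentiation bias.
    """

    zeta: float = 1.0
    alpha_q: float = 1.2
    orientation_q: str | None = None

    def __post_init__(self) -> None:
        if self.zeta == 0:
            raise ValueError("zeta must be non-zero")
        if self.alpha_q <= 0:
            raise ValueError("alpha_q must be positive")
        orient = self.orientation_q
        if orient is None:
            orient = "reverse" if self.zeta < 0 else "classical"
        if orient not in ("classical", "reverse"):
            raise ValueError("orientation_q must be 'classical' or 'reverse'")
        object.__setattr__(self, "orientation_q", orient)


@dataclass(frozen=True)
class HigherInputParams:
    """External stimulus drive delivered to the higher layer.

    The higher-layer input strengths are sampled exactly like the
    lower-layer ones, from their own cross-correlation matrix, and scaled by
    ``strength_ratio`` relative to the lower-layer mean.
    """

    strength_ratio: float = 1.0
    C_higher: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strength_ratio < 0:
            raise ValueError("strength_ratio must be non-negative")

    def C_sqrt(self, n: int, rng: np.random.Generator) -> np.ndarray:
        C = self.C_higher
        if C is None:
            C = build_input_correlation(n, rng)
        return correlation_sqrt(np.asarray(C, float))


def multiplicative_stdp_factors(
    w: np.ndarray | float, w_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weight-dependent gain of the potentiating and depressing sides.

    ``pot = (w_max - w) / w_max`` and ``dep = |w| / w_max``; both are
    applied entry-wise to the respective pair-sum accumulations.  At the
    ceiling potentiation stops, at zero depression stops.  The factors are
    normalized by the bound so they are order one (an unnormalized variant
    multiplies the effective learning rate by up to ``w_max`` and slams
    every weight into the hard bounds within a few presentations).
    """
    w = np.asarray(w, dtype=float)
    return (w_max - w) / w_max, np.abs(w) / w_max


def homeostatic_rescale(
    W: np.ndarray,
    input_gain: np.ndarray,
    mean_rates: np.ndarray,
    params: HomeostasisParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One application of homeostatic synaptic scaling.

    Per lower neuron ``i`` the factor is

        f_i = clip(1 + eta_eff * (F - r_i) / F, 0.5, 2)

    which equals 1 at the set point, exceeds 1 below it and shrinks the
    neuron's total input gain above it.  The clip guards both very strong
    settings and silent neurons (``r_i = 0``).  Row ``i`` of the top-down
    matrix and the neuron's external-input gain are multiplied by ``f_i``.
    """
    r = np.asarray(mean_rates, dtype=float)
    f = 1.0 + params.eta_eff * (params.target_rate - r) / params.target_rate
    f = np.clip(f, *_HOMEO_CLIP)
    return W * f[:, None], np.asarray(input_gain, float) * f


def concurrent_bottom_up_delta_linear(
    rule, params: ConcurrentParams,
    post_pre: np.ndarray, pre_post: np.ndarray,
) -> np.ndarray:
    """Bottom-up weight change for the linear engine.

    The same joint-activity pair sums drive both updates, with the roles of
    pre and post exchanged: for a bottom-up synapse the lower layer is
    pre-synaptic, so lower-before-higher pairs (``post_pre`` in top-down
    bookkeeping) are its pre-before-post side.
    """
    rate = abs(params.zeta) * rule.mu
    pre_post_q = post_pre.T   # lower fired first
    post_pre_q = pre_post.T   # higher fired first
    if params.orientation_q == "classical":
        return rate * (pre_post_q - params.alpha_q * post_pre_q)
    return rate * (post_pre_q - params.alpha_q * pre_post_q)
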