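"""Correlated stimulus ensembles and their temporal envelope.

External input reaches the lower area only.  Across stimulus presentations
the per-neuron input strengths are correlated Gaussian draws with a
prescribed cross-correlation matrix; within a presentation the drive follows
a stereotyped time course (a transient Gaussian bump followed by a weaker
tonic tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Envelope",
    "StimulusEnsemble",
    "build_input_correlation",
    "correlation_sqrt",
    "sample_input_strengths",
    "input_time_course",
]


@dataclass(frozen=True)
class Envelope:
    """Within-presentation time course of the external drive.

    The drive rises as a Gaussian transient of unit height centred at
    ``gauss_center_ms``, then holds at ``tonic_level`` (one fifth of the
    transient peak) from ``transient_ms`` until the presentation ends.
    """

    gauss_center_ms: float = 30.0
    gauss_width_ms: float = 20.0
    gauss_height: float = 1.0
    tonic_level: float = 0.2
    transient_ms: float = 80.0
    presentation_ms: float = 160.0

    def __post_init__(self) -> None:
        if min(self.gauss_width_ms, self.presentation_ms) <= 0:
            raise ValueError("envelope durations must be positive")
        if self.gauss_height < 0 or self.tonic_level < 0:
            raise ValueError("envelope levels must be non-negative")
        if self.transient_ms > self.presentation_ms:
            raise ValueError("transient phase cannot outlast the presentation")


def input_time_course(t_ms: float | np.ndarray, envelope: Envelope | None = None) -> np.ndarray:
    """Evaluate the stimulus envelope at time ``t_ms`` (ms from onset).

    Outside ``[0, presentation_ms)`` the drive is zero.
    """
    env = envelope or Envelope()
    t = np.asarray(t_ms, dtype=float)
    gauss = env.gauss_height * np.exp(
        -0.5 * ((t - env.gauss_center_ms) / env.gauss_width_ms) ** 2
    )
    out = np.where(t < env.transient_ms, gauss, env.tonic_level)
    out = np.where((t < 0) | (t >= env.presentation_ms), 0.0, out)
    return out if out.ndim else float(out)


def build_input_correlation(
    n: int,
    rng: np.random.Generator | int | None = None,
    ensemble_factor: int = 2,
) -> np.ndarray:
    """Random symmetric positive-semidefinite matrix with unit diagonal.

    Built as the sample correlation of ``ensemble_factor * n`` independent
    Gaussian vectors, i.e. ``A @ A.T`` rescaled to unit diagonal.  The
    ensemble factor controls how far the matrix sits from singularity: with
    a factor of at least two the spectrum is comfortably bounded away from
    zero, mimicking the correlation structure of a generic stimulus set.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n == 1:
        return np.ones((1, 1))
    rng = np.random.default_rng(rng)
    A = rng.standard_normal((n, ensemble_factor * n))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def correlation_sqrt(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric square root of a PSD correlation matrix.

    Used to colour i.i.d. normal draws so that their correlation matches
    ``C``.  Raises if ``C`` is not symmetric PSD within ``tol``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -tol:
        raise ValueError(f"C is not positive semidefinite (min eigenvalue {evals.min():.2e})")
    return (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T


@dataclass(frozen=True)
class StimulusEnsemble:
    """Distribution of per-presentation input strengths to the lower area.

    Each presentation draws a strength vector ``J`` with mean ``j_mean``
    (spikes/s), entries correlated according to ``C`` and rectified at zero.
    ``rel_spread`` sets the across-presentation standard deviation as a
    fraction of the mean.  ``sigma_input`` is the *within*-presentation
    noisiness: at each time step the momentary rate is redrawn around
    ``J_i * envelope(t)`` with standard deviation ``sigma_input`` times that
    product.
    """

    C: np.ndarray
    j_mean: float = 20_000.0
    rel_spread: float = 0.5
    sigma_input: float = 1.0
    envelope: Envelope = field(default_factory=Envelope)

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "_C_sqrt", correlation_sqrt(C))
        if self.j_mean <= 0:
            raise ValueError("j_mean must be positive")
        if self.rel_spread < 0 or self.sigma_input < 0:
            raise ValueError("spread parameters must be non-negative")

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def C_sqrt(self) -> np.ndarray:
        return self._C_sqrt  # type: ignore[attr-defined]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return sample_input_strengths(
            self.C, self.j_mean, rng, rel_spread=self.rel_spread, C_sqrt=self.C_sqrt
        )


def sample_input_strengths(
    C: np.ndarray,
    j_mean: float,
    rng: np.random.Generator | int | None = None,
    rel_spread: float = 0.5,
    C_sqrt: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one correlated, rectified input-strength vector.

    The vector is ``j_mean + rel_spread * j_mean * (C^{1/2} z)`` with
    ``z ~ N(0, I)``, clipped at zero.  Across many draws the empirical
    correlation converges to ``C`` up to the (small, positive) bias
    introduced by the rectification.
    """
    rng = np.random.default_rng(rng)
    if C_sqrt is None:
        C_sqrt = correlation_sqrt(C)
    z = rng.standard_normal(C_sqrt.shape[0])
    J = j_mean + rel_spread * j_mean * (C_sqrt @ z)
    return np.clip(J, 0.0, None)
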