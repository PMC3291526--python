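"""Generation and diagnostics of the inter-areal weight matrices.

The model couples two neural populations: a lower area whose activity is
driven by external stimuli, and a higher area driven only through the
bottom-up weights ``Q`` (shape ``n_higher x n_lower``).  Activity returns to
the lower area through the top-down weights ``W`` (shape
``n_lower x n_higher``), the quantity whose development the package studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import polar
from scipy.ndimage import gaussian_filter

__all__ = [
    "NetworkMatrices",
    "generate_bottom_up_matrix",
    "loop_gain_spectrum",
    "strong_loop",
]

logger = logging.getLogger(__name__)

#: Every generated bottom-up matrix is rescaled so its largest entry equals
#: this constant.
Q_SCALE = 5.0

# Column means of the pre-normalization matrix below this magnitude make the
# column normalization blow up; such draws are rejected and regenerated.
_DEGENERATE_COLUMN_MEAN = 1e-6
_MAX_RETRIES = 20


@dataclass(frozen=True)
class NetworkMatrices:
    """Conjugate pair of bottom-up (``Q``) and top-down (``W``) weights.

    ``Q`` maps lower-area activity to the higher area (``H = Q @ L``) and has
    shape ``(n_higher, n_lower)``; ``W`` maps back down (``L = W @ H``) and
    has shape ``(n_lower, n_higher)``.
    """

    Q: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        W = np.asarray(self.W, dtype=float)
        if Q.ndim != 2 or W.ndim != 2:
            raise ValueError("Q and W must be matrices")
        if Q.shape != (W.shape[1], W.shape[0]):
            raise ValueError(
                f"shapes are not conjugate: Q {Q.shape}, W {W.shape}"
            )
        if not (np.isfinite(Q).all() and np.isfinite(W).all()):
            raise ValueError("Q and W must be finite-valued")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "W", W)

    @property
    def n_lower(self) -> int:
        return self.Q.shape[1]

    @property
    def n_higher(self) -> int:
        return self.Q.shape[0]


def generate_bottom_up_matrix(
    n_lower: int,
    n_higher: int,
    epsilon: float = 0.1,
    smooth_width: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw a well-conditioned random bottom-up weight matrix.

    The construction starts from a uniformly distributed random matrix
    (optionally blurred with a circular Gaussian filter for smoother
    structure), takes its polar decomposition ``R = U P``, and perturbs the
    unitary factor, ``Q_raw = U + epsilon * P``.  Because ``U`` has condition
    number one and ``epsilon`` is small, the result stays far from
    singularity, which matters because the learned top-down weights approach
    a multiple of ``Q``'s inverse.  Finally each column is divided by its
    mean and the whole matrix rescaled so that its maximum entry is exactly
    ``Q_SCALE``.

    Parameters
    ----------
    n_lower, n_higher:
        Populations sizes; ``Q`` has shape ``(n_higher, n_lower)``.
    epsilon:
        Weight of the positive-semidefinite polar factor, ``> 0``.
    smooth_width:
        Standard deviation, in matrix cells, of the periodic Gaussian blur
        applied to the raw random matrix; ``None`` disables smoothing.
    rng:
        Seed or generator.

    Returns
    -------
    ndarray of shape ``(n_higher, n_lower)`` whose maximum entry equals 5.
    """
    if n_lower < 1 or n_higher < 1:
        raise ValueError("population sizes must be at least 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(rng)

    for attempt in range(_MAX_RETRIES):
        R = rng.uniform(size=(n_higher, n_lower))
        if smooth_width is not None:
            R = gaussian_filter(R, sigma=smooth_width, mode="wrap")
        try:
            U, P = polar(R)
        except np.linalg.LinAlgError:  # pragma: no cover - scipy rarely fails
            logger.warning("polar decomposition failed; redrawing (try %d)", attempt)
            continue
        if n_higher == n_lower:
            Q_raw = U + epsilon * P
        else:
            # For rectangular matrices U and P are not conformable for
            # addition; perturb the partial isometry inside its row space.
            Q_raw = U + epsilon * (U @ P)
        col_means = Q_raw.mean(axis=0)
        if np.abs(col_means).min() < _DEGENERATE_COLUMN_MEAN:
            logger.warning(
                "degenerate column mean in Q draw; redrawing (try %d)", attempt
            )
            continue
        Q = Q_raw / col_means
        Q = Q / Q.max() * Q_SCALE
        return Q
    raise RuntimeError(
        f"failed to generate a non-degenerate bottom-up matrix in {_MAX_RETRIES} draws"
    )


def loop_gain_spectrum(Q: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Eigenvalues of the round-trip matrix ``W @ Q``.

    One application of ``W @ Q`` maps lower-area activity through the higher
    area and back; eigenvalues of modulus above one mean some activity
    pattern is amplified on every loop (a "strong loop").
    """
    Q = np.asarray(Q, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape[1] != Q.shape[0]:
        raise ValueError(f"W {W.shape} and Q {Q.shape} are not conformable")
    return np.linalg.eigvals(W @ Q)


def strong_loop(Q: np.ndarray, W: np.ndarray, limit: float = 1.0) -> bool:
    """True when the loop gain exceeds ``limit`` in modulus."""
    eig = loop_gain_spectrum(Q, W)
    return bool(np.abs(eig).max(initial=0.0) > limit)
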