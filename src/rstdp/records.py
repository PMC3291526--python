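"""Outcome labels shared by the linear and spiking engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["CONVERGED", "EXTREME_WEIGHTS", "WEIGHTS_TOO_SIMILAR", "DID_NOT_CONVERGE",
           "LABELS", "OutcomeRecord"]

CONVERGED = "converged"
EXTREME_WEIGHTS = "extreme_weights"
WEIGHTS_TOO_SIMILAR = "weights_too_similar"
DID_NOT_CONVERGE = "did_not_converge"

#: The four mutually exclusive outcomes of a training run.  A run counts as
#: converged only when the weights are simultaneously stable (unchanging),
#: diverse (spread-out distribution) and weak (no strong loops / not pinned
#: at the bounds); each failure mode gets its own label.
LABELS = (CONVERGED, EXTREME_WEIGHTS, WEIGHTS_TOO_SIMILAR, DID_NOT_CONVERGE)


@dataclass
class OutcomeRecord:
    """Classification of one training run plus the supporting diagnostics."""

    label: str
    n_stop: int
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown outcome label {self.label!r}")
        if self.n_stop < 0:
            raise ValueError("n_stop must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {"label": self.label, "n_stop": self.n_stop,
                "diagnostics": dict(self.diagnostics)}
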