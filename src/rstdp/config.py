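"""Run configuration, validation and deterministic seed derivation.

Configs are flat key/value text files (``key = value`` per line, ``#``
comments), using the short parameter names of the simulation sweep grid.
Unknown keys are rejected so that typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "SeedRegistry", "load_config", "save_config"]


_ALLOWED_RANGES = {
    "alpha": (0.0, 100.0),
    "a_plus": (0.0, 1.0),
    "tau_stdp_ms": (0.0, 1000.0),
    "tau_syn_ms": (0.0, 1000.0),
    "d_ms": (1.0, 1000.0),
    "S": (0.0, 1e6),
    "sigma_input": (0.0, 10.0),
    "sigma_noise": (0.0, 10.0),
    "w_max": (0.0, 1e4),
    "n_lower": (1, 10_000),
    "n_higher": (1, 10_000),
    "mu": (0.0, 1.0),
    "max_presentations": (1, 10_000_000),
    "target_rate_F": (0.0, 1e4),
    "strength_eta": (0.0, 1e4),
    "zeta": (-1e3, 1e3),
    "alpha_q": (0.0, 100.0),
    "higher_ratio": (0.0, 100.0),
    "seed": (0, 2**31 - 1),
    "epsilon": (0.0, 100.0),
    "j_rel_spread": (0.0, 10.0),
    "v_thresh": (-100.0, 50.0),
}

_ENUMS = {
    "engine": ("linear", "spiking"),
    "orientation": ("classical", "reverse"),
    "orientation_q": ("classical", "reverse", "from_zeta"),
    "update_mode": ("expected", "per_stimulus"),
    "variant": ("none", "homeostatic", "multiplicative", "concurrent",
                "higher_input"),
}


@dataclass
class RunConfig:
    """Validated flat description of a single training run."""

    engine: str = "spiking"
    orientation: str = "reverse"
    alpha: float = 1.2
    n_lower: int = 100
    n_higher: int = 100
    seed: int = 0
    # spiking-engine parameters (sweep-grid names)
    a_plus: float = 0.01
    tau_stdp_ms: float = 20.0
    d_ms: float = 15.0
    S: float = 2000.0
    tau_syn_ms: float = 15.0
    sigma_input: float = 1.0
    sigma_noise: float = 1.0
    w_max: float = 50.0
    v_thresh: float = -54.0
    j_rel_spread: float = 0.5
    max_presentations: int = 625_000
    # linear-engine parameters
    mu: float = 2.5e-4
    update_mode: str = "expected"
    epsilon: float = 0.1
    smooth_width: float | None = None
    # variant block
    variant: str = "none"
    target_rate_F: float = 80.0
    strength_eta: float = 1.0
    zeta: float = 1.0
    alpha_q: float = 1.2
    orientation_q: str = "from_zeta"
    higher_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name, allowed in _ENUMS.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"config key '{name}': {value!r} not in {allowed}")
        for name, (lo, hi) in _ALLOWED_RANGES.items():
            attr = name if hasattr(self, name) else None
            if attr is None:
                continue
            value = getattr(self, attr)
            if value is None:
                continue
            if not (lo <= value <= hi):
                raise ValueError(
                    f"config key '{name}': value {value!r} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _parse_scalar(raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a key/value config file."""
    path = Path(path)
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, raw = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key = key.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key '{key}'")
        values[key] = _parse_scalar(raw)
    return RunConfig(**values)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config in the same key/value dialect that load_config reads."""
    lines = [f"{k} = {v if v is not None else 'none'}"
             for k, v in config.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


class SeedRegistry:
    """Deterministic derivation of independent per-run random streams.

    Child streams are derived from the master seed and a tuple of string /
    integer labels, so the same (master, labels) pair always yields the
    same stream and distinct labels yield independent streams.
    """

    def __init__(self, master_seed: int):
        if not 0 <= master_seed < 2**63:
            raise ValueError("master seed must be a non-negative 63-bit integer")
        self.master_seed = int(master_seed)

    def _sequence(self, *labels: str | int) -> np.random.SeedSequence:
        import zlib

        key = tuple(
            zlib.crc32(str(label).encode()) if isinstance(label, str) else int(label)
            for label in labels
        )
        return np.random.SeedSequence(entropy=self.master_seed, spawn_key=key)

    def generator(self, *labels: str | int) -> np.random.Generator:
        return np.random.default_rng(self._sequence(*labels))

    def seed(self, *labels: str | int) -> int:
        """A plain integer seed below 2**31 for APIs that need one."""
        return int(self._sequence(*labels).generate_state(1, np.uint32)[0] % (2**31))
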