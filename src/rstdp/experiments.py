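"""Parameter sweeps, outcome tabulation and the input-reconstruction probe.

The sweep engine runs the spiking trainer over a parameter grid and counts
outcomes per learning-rule class.  The four classes cross the rule
orientation (classical / reverse) with the depression bias (``alpha > 1``
depression-biased, ``alpha < 1`` potentiation-biased).

The reconstruction probe asks what the trained top-down weights compute: a
brief input transient is presented, and the late-window activity (driven
purely through the loop via the top-down weights) is compared against the
early stimulus-driven activity pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .lif import LIFConfig
from .networks import generate_bottom_up_matrix
from .spiking import (SpikingRuleSpec, SpikingStopCriteria,
                      run_presentation_spiking, train_spiking)
from .stimulus import Envelope, StimulusEnsemble, build_input_correlation

__all__ = [
    "SweepSpec",
    "desk_sweep_spec",
    "run_parameter_sweep",
    "summarize_outcomes",
    "rule_class",
    "reconstruction_transform_Q",
    "reconstruction_experiment",
    "ReconstructionResult",
]

logger = logging.getLogger(__name__)

# Full parameter grid of the spiking-engine sweep.
FULL_GRID: dict[str, tuple] = {
    "orientation": ("reverse", "classical"),
    "alpha": (0.9, 1.2, 3.0),
    "delay_ms": (1, 15),
    "tau_stdp_ms": (5.0, 10.0, 20.0),
    "noise_mean": (1000.0, 2000.0),
    "tau_syn_ms": (5.0, 15.0),
    "sigma_input": (1.0, 2.0),
    "sigma_noise": (1.0, 2.0),
}


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a batch of spiking training runs."""

    grid: dict[str, tuple] = field(default_factory=lambda: dict(FULL_GRID))
    replicates: int = 3
    n_neurons: int = 100
    w_max: float = 50.0
    max_presentations: int = 625_000

    def cells(self) -> list[dict]:
        names = list(self.grid)
        return [dict(zip(names, combo)) for combo in product(*self.grid.values())]

    @property
    def n_runs(self) -> int:
        return len(self.cells()) * self.replicates


def desk_sweep_spec(
    n_neurons: int = 30, max_presentations: int = 150_000
) -> SweepSpec:
    """Reduced sweep that preserves the categorical contrast at desk scale.

    All four rule classes run over the sub-grid
    ``alpha x tau_STDP x delay x tau_syn`` with the remaining parameters at
    mid-grid values.  The presentation cap is set from the observed
    equilibration time of the weight distribution at this network size
    (comparable to the full-scale model, on the order of 1e5 presentations),
    so that slow-but-stable cells are not misread as non-convergent.
    """
    grid = {
        "orientation": ("reverse", "classical"),
        "alpha": (0.9, 1.2, 3.0),
        "tau_stdp_ms": (10.0, 20.0),
        "delay_ms": (1, 15),
        "tau_syn_ms": (5.0, 15.0),
    }
    return SweepSpec(grid=grid, replicates=3, n_neurons=n_neurons,
                     max_presentations=max_presentations)


def rule_class(orientation: str, alpha: float) -> str:
    """Assign a run to one of the four learning-rule classes."""
    kind = "rSTDP" if orientation == "reverse" else "cSTDP"
    bias = "depression" if alpha > 1.0 else "potentiation"
    return f"{kind}-{bias}"


def _run_key(cell: dict, rep: int) -> str:
    return "|".join(f"{k}={cell[k]}" for k in sorted(cell)) + f"|rep={rep}"


def run_parameter_sweep(
    spec: SweepSpec,
    seed: int = 0,
    progress: bool = False,
    resume_path: str | None = None,
) -> pd.DataFrame:
    """Execute every cell of the sweep and return one row per run.

    Each (cell, replicate) pair gets an independent seed stream derived
    from ``seed``; the bottom-up matrix and the stimulus correlation matrix
    are redrawn per run, as are the initial top-down weights.  A crashed
    cell is recorded with label ``error`` instead of aborting the sweep.

    With ``resume_path`` set, finished runs are checkpointed to that CSV
    after every cell and already-completed (cell, replicate) pairs are
    skipped on a re-run.
    """
    done: dict[str, dict] = {}
    if resume_path is not None:
        try:
            prev = pd.read_csv(resume_path)
            done = {row.pop("run_key"): row
                    for row in prev.to_dict(orient="records")}
        except FileNotFoundError:
            pass
    rows = []
    cells = spec.cells()
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(cells) * spec.replicates)
    idx = 0
    for cell in cells:
        for rep in range(spec.replicates):
            key = _run_key(cell, rep)
            if key in done:
                rows.append(dict(done[key]))
                idx += 1
                continue
            rng = np.random.default_rng(streams[idx])
            idx += 1
            row = dict(cell, replicate=rep,
                       rule_class=rule_class(cell["orientation"], cell["alpha"]))
            try:
                Q = generate_bottom_up_matrix(spec.n_neurons, spec.n_neurons,
                                              epsilon=0.1, rng=rng)
                C = build_input_correlation(spec.n_neurons, rng)
                ensemble = StimulusEnsemble(
                    C, sigma_input=cell.get("sigma_input", 1.0))
                lif = LIFConfig(
                    tau_syn_ms=cell.get("tau_syn_ms", 15.0),
                    delay_ms=cell.get("delay_ms", 15),
                    noise_mean=cell.get("noise_mean", 2000.0),
                    sigma_noise=cell.get("sigma_noise", 1.0),
                )
                rule = SpikingRuleSpec(
                    orientation=cell["orientation"], alpha=cell["alpha"],
                    tau_stdp_ms=cell.get("tau_stdp_ms", 20.0),
                    w_max=spec.w_max)
                crit = SpikingStopCriteria(
                    max_presentations=spec.max_presentations)
                _, outcome, trace, _ = train_spiking(
                    Q, ensemble, rule, lif=lif, criteria=crit, rng=rng)
                row.update(label=outcome.label, n_stop=outcome.n_stop,
                           final_std=outcome.diagnostics["final_std"],
                           mean_rate=outcome.diagnostics["mean_rate_lower"])
            except Exception:  # noqa: BLE001 - sweep must survive bad cells
                logger.exception("sweep cell failed: %r", cell)
                row.update(label="error", n_stop=0,
                           final_std=np.nan, mean_rate=np.nan)
            rows.append(row)
            if progress:
                logger.info("sweep %d/%d: %s", idx, len(streams), row["label"])
            if resume_path is not None:
                ck = pd.DataFrame(rows)
                ck.insert(0, "run_key", [
                    _run_key({k: r[k] for k in cell}, r["replicate"])
                    for r in rows])
                ck.to_csv(resume_path, index=False)
    out = pd.DataFrame(rows)
    return out.drop(columns=["run_key"], errors="ignore")


def summarize_outcomes(result: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each outcome label within each learning-rule class."""
    if result.empty:
        raise ValueError("empty sweep result")
    counts = result.groupby(["rule_class", "label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def reconstruction_transform_Q(Q: np.ndarray) -> np.ndarray:
    """Shift the bottom-up matrix into the weak-drive regime.

    ``Q' = 2 Q - mean(2 Q) + 0.5`` (scalar mean over all entries); the
    result always has overall mean 0.5, so that only neurons with stronger
    inputs are driven to fire.
    """
    Q2 = 2.0 * np.asarray(Q, dtype=float)
    return Q2 - Q2.mean() + 0.5


@dataclass
class ReconstructionResult:
    """Reconstruction quality per training checkpoint.

    ``corr_mean[k]`` / ``corr_std[k]`` summarize, over the probe stimuli,
    the Pearson correlation between early-window spike counts and
    baseline-subtracted late-window counts at checkpoint
    ``checkpoints[k]``.  ``flagged[k]`` counts probe stimuli whose late
    activity had zero variance (correlation defined as 0 there).
    """

    checkpoints: list[int]
    corr_mean: list[float]
    corr_std: list[float]
    flagged: list[int]
    per_stimulus: np.ndarray  # (n_checkpoints, n_stimuli)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"checkpoint": self.checkpoints,
                             "corr_mean": self.corr_mean,
                             "corr_std": self.corr_std,
                             "n_flagged": self.flagged})


def _window_counts(record, t0_ms: float, t1_ms: float) -> np.ndarray:
    raster = record.lower_spikes
    dt = record.dt_ms
    i0, i1 = int(t0_ms / dt), int(t1_ms / dt)
    return raster[:, i0:i1].sum(axis=1).astype(float)


def reconstruction_experiment(
    Q: np.ndarray,
    ensemble: StimulusEnsemble,
    rule: SpikingRuleSpec,
    lif: LIFConfig | None = None,
    checkpoints: list[int] | None = None,
    n_stimuli: int = 100,
    rng: np.random.Generator | int | None = None,
    max_presentations: int | None = None,
    early_window_ms: tuple[float, float] = (0.0, 50.0),
    late_window_ms: tuple[float, float] = (80.0, 160.0),
    W0: np.ndarray | None = None,
) -> ReconstructionResult:
    """Measure input reconstruction through the top-down weights.

    The network is trained with snapshots of ``W`` at the requested
    checkpoints.  Each checkpoint is then probed with ``n_stimuli`` fixed
    stimuli under a truncated envelope (external drive zero after the early
    window): the per-neuron late-window spike counts, minus the counts of a
    ``W = 0`` control run of the same stimulus, are correlated with the
    early-window counts.  Training with depression-biased reverse STDP
    should make this correlation rise with training time.
    """
    lif = lif or LIFConfig()
    rng = np.random.default_rng(rng)
    checkpoints = sorted(checkpoints or [10, 100, 1000, 10_000, 51_000])
    cap = max_presentations or (checkpoints[-1] + 1)
    crit = SpikingStopCriteria(max_presentations=max(cap, 7000))

    _, outcome, _, snapshots = train_spiking(
        Q, ensemble, rule, lif=lif, criteria=crit, rng=rng, W0=W0,
        snapshot_at=checkpoints)
    missing = [N for N in checkpoints if N not in snapshots]
    if missing:
        logger.warning("run stopped at %d; checkpoints %s not reached",
                       outcome.n_stop, missing)
        checkpoints = [N for N in checkpoints if N in snapshots]

    probe_env = Envelope(transient_ms=early_window_ms[1], tonic_level=0.0,
                         presentation_ms=ensemble.envelope.presentation_ms)
    probe = StimulusEnsemble(ensemble.C, j_mean=ensemble.j_mean,
                             rel_spread=ensemble.rel_spread,
                             sigma_input=ensemble.sigma_input,
                             envelope=probe_env)
    stimuli = [probe.sample(rng) for _ in range(n_stimuli)]
    seeds = rng.integers(0, 2**31, size=n_stimuli)

    W_zero = np.zeros((Q.shape[1], Q.shape[0]))
    per = np.zeros((len(checkpoints), n_stimuli))
    flagged = [0] * len(checkpoints)
    for s, (j_bar, probe_seed) in enumerate(zip(stimuli, seeds)):
        # identical noise stream for the probe and its W = 0 control
        rec0 = run_presentation_spiking(
            W_zero, Q, lif, probe, j_bar, np.random.default_rng(probe_seed))
        base_late = _window_counts(rec0, *late_window_ms)
        for k, N in enumerate(checkpoints):
            rec = run_presentation_spiking(
                snapshots[N], Q, lif, probe, j_bar,
                np.random.default_rng(probe_seed))
            early = _window_counts(rec, *early_window_ms)
            late = _window_counts(rec, *late_window_ms) - base_late
            if late.std() == 0 or early.std() == 0:
                flagged[k] += 1
                per[k, s] = 0.0
            else:
                per[k, s] = float(np.corrcoef(early, late)[0, 1])
    return ReconstructionResult(
        checkpoints=checkpoints,
        corr_mean=[float(per[k].mean()) for k in range(len(checkpoints))],
        corr_std=[float(per[k].std()) for k in range(len(checkpoints))],
        flagged=flagged,
        per_stimulus=per,
    )
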