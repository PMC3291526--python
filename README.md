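# rstdp

Simulation toolkit for studying **which spike-timing-dependent plasticity
(STDP) rule can wire up the top-down (feedback) connections of a cortical
hierarchy** without destabilizing it.

Sensory drive reaches a lower cortical area before a higher one, so a
top-down synapse — whose *pre*-synaptic neuron sits in the higher area —
mostly experiences post-before-pre spike pairs.  This package implements a
two-layer model of reciprocally connected populations (bottom-up weights
**Q**, plastic top-down weights **W**) in two forms:

* a **linear rate model** whose per-presentation expected weight update can
  be written in closed form and whose fixed points can be computed exactly;
* a **noisy conductance-based leaky integrate-and-fire network** with
  millisecond spike timing, transmission delays, and an exponential-window
  pair-based STDP rule.

Both engines train **W** under classical STDP (pre-before-post potentiates)
or temporally reversed STDP (*rSTDP*: post-before-pre potentiates), with a
depression/potentiation bias α (α > 1 = depression-biased; the depressing
side is always scaled by α).  Each training run is classified as
`converged` (weights stable, diverse and weak), `extreme_weights`,
`weights_too_similar`, or `did_not_converge`.

The central, reproducible result: **only depression-biased rSTDP produces
top-down weights that are simultaneously stable, diverse and weak.**  In
the linear model the learned weights converge onto the scaled inverse
**W\* = Q⁻¹/α**, whose loop gain (eigenvalues of **WQ**) equals 1/α — the
circuit provably avoids strong loops — while classical STDP has no stable
fixed point at all.  Rule modifications (homeostatic synaptic scaling,
multiplicative soft-bound STDP, concurrent bottom-up plasticity, external
input to the top layer) are implemented for both engines and do not rescue
classical STDP.  Trained feedback weights reconstruct the network's input
from late, feedback-driven activity.

See `docs/methods.md` for model equations, parameter choices, numerical
decisions and desk-scale caveats.

## Worked example

Train the 20×20 linear network with depression-biased rSTDP (α = 3) and
check the three claims directly:

```python
import numpy as np
from rstdp import (LinearRuleSpec, LinearStimulus, NetworkMatrices,
                   build_input_correlation, generate_bottom_up_matrix,
                   train_linear)
from rstdp.linear import initial_top_down

rng = np.random.default_rng(101)
Q = generate_bottom_up_matrix(20, 20, epsilon=0.1, smooth_width=3, rng=rng)
C = build_input_correlation(20, rng)
W0 = initial_top_down(20, 20, rng=rng)

net, outcome, trace = train_linear(
    NetworkMatrices(Q, W0), LinearStimulus(C),
    LinearRuleSpec(orientation="reverse", alpha=3.0), rng=rng)

print(outcome.label, outcome.n_stop)
print("corr(W, Q^-1) =", round(np.corrcoef(net.W.ravel(),
                                           np.linalg.inv(Q).ravel())[0, 1], 4))
print("max loop gain over run =", round(trace["max_eig_mod"].max(), 4))
```

```
converged 1494
corr(W, Q^-1) = 1.0
max loop gain over run = 0.3333
```

The run converges after ~1.5·10³ stimulus presentations; the learned
top-down matrix is (up to scale) the inverse of the bottom-up matrix, and
the loop gain never exceeds 1/α = 1/3 at any point during learning — the
feedback stays weak while it organizes.  Swapping
`orientation="classical"` makes the same network blow through the
loop-gain limit and end as `extreme_weights`.

The spiking engine has the same shape of API
(`rstdp.train_spiking`), a sweep driver over the parameter grid
(`rstdp.run_parameter_sweep`, `rstdp.desk_sweep_spec`) and the
input-reconstruction probe (`rstdp.reconstruction_experiment`).

## Command line

```bash
rstdp simulate --config run.cfg --out out/      # one training run
rstdp sweep --scale desk --seed 0 --out sweep/  # outcome proportions per rule class
rstdp reconstruct --config run.cfg --out rec/   # input-reconstruction probe
rstdp classify --weights out/weights.h5         # re-classify a saved history
```

Configs are flat `key = value` text files; unknown keys are rejected.  See
`rstdp.config.RunConfig` for the key names and defaults.

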