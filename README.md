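# netres

Uncertainty quantification of multi-scale resilience in networked nonlinear
dynamical systems, using moment-based (arbitrary) polynomial chaos.

A networked system `dx_i/dt = f(x_i, a) + Σ_j M_ji g(x_i, x_j, b)` is reduced
to a one-dimensional effective equation whose local-minimum value `τ` signals
resilience: `τ > 0` exactly when only the healthy equilibrium survives.
`netres` quantifies how parameter and observation uncertainty propagate into
that indicator at two resolutions:

- **Network level** — with iid-per-node uncertain parameters, node averages
  become Gaussian (CLT) and the whole effective curve is driven by one
  standard normal `ζ`; `τ(ζ)` is expanded in Hermite polynomials and
  `P(τ > 0)` is evaluated analytically from the surrogate's roots.
- **Node level** — a two-step sequential estimator: the mean-field healthy
  equilibrium stands in for every neighbor, each node reduces to a single
  equation driven by its in-weight, and the node indicator `τ_i(ξ_1..ξ_l)` is
  expanded in orthonormal polynomials built **directly from the raw moments**
  of the input distributions (arbitrary polynomial chaos) — named families,
  empirical samples and bare moment sequences all work. A direct Monte Carlo
  estimator provides the reference baseline.

Also included: saddle-node threshold detection (`w*`), critical-weight curves
`w_crit(w_av)`, observation-noise closed forms, two case-study models
(bistable mutualistic dynamics and a competitive commuter model), and a
workbench for synthetic networks, sweeps and order/accuracy reports.

## Library quick start

```python
import numpy as np
from netres import Mutualistic, RandomInput, meanfield, node_uq
from netres.workbench import NetworkRecipe, generate_network

graph = generate_network(NetworkRecipe("erdos-renyi", 100, density=0.15,
                                       target_w_av=6.9, seed=1))
model = Mutualistic(params=dict(
    B=0.1, C=RandomInput.uniform(0.9, 1.1, "C"), K=5.0,
    D=5.0, E=RandomInput.uniform(0.81, 0.99, "E"), H=0.1), mode="shared")

# bifurcation threshold of the deterministic mean field
w_star = meanfield.critical_threshold(
    Mutualistic(params=dict(B=0.1, C=1.0, K=5.0, D=5.0, E=0.9, H=0.1)),
    bracket=(3.0, 12.0)).w_star

# node-level resilience probability via the aPC surrogate
surrogate = node_uq.fit_node_apc(model, graph, node=0, order=3, seed=0)
report = node_uq.node_resilience_probability(
    surrogate, model.uncertain_inputs, n_samples=1_000_000, seed=0)
print(w_star, report.probability)
```

## CLI

Installed as `netres` (see `netres --help`):

```
netres critical-curve --config run.yaml --wav-grid 1:12:0.25 --output curve.csv
netres network-uq     --config run.yaml --order 3 --output net.json
netres node-uq        --config run.yaml --nodes 0,5 --order 3 --output nodes.csv
netres sweep          --config run.yaml --output sweep.csv
netres report         --config run.yaml --output order_report.csv
netres simulate       --config run.yaml --horizon 50 --output traj.csv
netres generate       --family erdos-renyi --n 100 --target-wav 6.9 --output net.csv
```

A run configuration is YAML, e.g.

```yaml
model:
  name: mutualistic         # mutualistic | bistable | commuter
  params: {B: 0.1, C: 1.0, K: 5.0, D: 5.0, E: 0.9, H: 0.1}
uncertainty:
  mode: shared              # shared | iid (one draw vs per-node copies)
  parameters:
    C: {kind: uniform, lower: 0.9, upper: 1.1}
    E: {samples_file: e_samples.txt}    # or  {moments: [1, 0.9, 0.83, ...]}
network: {family: erdos-renyi, N: 100, density: 0.15, seed: 1, target_w_av: 6.9}
sweep: {start: 5.0, stop: 9.0, step: 0.25}
```

Networks may also be loaded from file: `network: {file: net.csv}` with an
edge-list CSV (`source,target,weight`, 0-based ids, a row meaning "source
influences target") or `format: adjacency` for a square CSV with entry
(row j, column i) = M_ji.

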