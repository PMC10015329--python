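# netews — early warning signals for multi-stage tipping on networks

Networked systems — interconnected ecosystems, climate basins, social
groups — often do not tip all at once. As a control parameter drifts, some
nodes jump from one stable state to the other while the rest hold out, so
the system passes through a *multi-stage* transition: a staircase of abrupt
shifts separated by quiet plateaus. `netews` is a simulation and analysis
toolkit for asking, on such systems, **which nodes should be monitored to
anticipate the next stage, and with which statistic**.

It is aimed at researchers studying tipping points and critical slowing
down on networks: it simulates the dynamics, computes the standard early
warning signals from configurable "sentinel" node sets, and scores every
signal/node-set combination.

## Model and method

Each node `i` of an undirected, unweighted network with adjacency matrix
`A = (a_ij)` follows coupled double-well stochastic dynamics,

```
dx_i/dt = -(x_i - r1)(x_i - r2)(x_i - r3) + D Σ_j a_ij x_j + u + s ξ_i
```

with equilibria controlled by `r1 < r2 < r3` (default 1, 4, 7), diffusive
coupling `D ≥ 0`, an optional uniform stressor `u`, and Gaussian white noise
of intensity `s`. A node is in the **lower** macro state when `x_i` is below
the smaller critical point of the cubic term (`4 - √3 ≈ 2.268` at default
parameters) and in the **upper** state otherwise; for upper-start sweeps the
larger critical point (`4 + √3 ≈ 5.732`) is used.

The pipeline:

1. **Sweep** the bifurcation parameter (`D` by default) quasi-statically:
   at each value, reset the state, relax 50 TU, then take `M = 250` samples
   over 25 TU (Euler–Maruyama, `Δt = 0.01`), stopping once more than 90% of
   nodes have transitioned.
2. **Stable ranges**: maximal runs of parameter values over which the
   number of upper-state nodes at equilibrium is constant.
3. **Signals**: for each node set at each parameter value, five early
   warning signals — the dominant covariance eigenvalue `λ_max`, and the
   max/mean of the per-node standard deviation and lag-1 autocorrelation.
4. **Sentinel node sets** (recomputed at every parameter value): All,
   Lower State, Upper State, High Input / Low Input (extremes of the input
   score `R_i = Σ_j a_ij x̄_j`), Lower Half, Random, Large Correlation
   (extremes of the network-free proxy `R'_i = Σ_{j≠i} cor(x_i, x_j) x̄_j`),
   and Large s.d. (`n = 5` for the fixed-size sets).
5. **Scoring**: Kendall rank correlation `τ` between the parameter and each
   signal within every stable range spanning at least 15 unique parameter
   values, averaged across ranges. High `τ` means the signal rose reliably
   towards each transition.

## Worked example

```python
import netews as ne

net = ne.generate_powerlaw_config(100, exponent=3.0, min_degree=2, seed=42)
print(f"network: {net.N} nodes, {net.n_edges} edges")

out = ne.run_ews_analysis(net, ne.DoubleWellParams(s=0.05), ne.SweepConfig(seed=42))
res = out["result"]
print(f"sweep: {len(res.blocks)} values of D; {res.termination_reason}")
qual = [r for r in out["ranges"] if r.qualifies]
print(f"stable ranges: {len(out['ranges'])} total, {len(qual)} qualifying (>= 15 unique D)")
for r in qual:
    print(f"  D in [{r.param_values[0]:.3f}, {r.param_values[-1]:.3f}]  "
          f"upper-state count {r.upper_count}")

tau = out["tau"].drop_duplicates(["node_set", "signal"])
core = tau[tau.node_set.isin(["all", "lower_state", "high_input"])]
print(core.pivot(index="node_set", columns="signal", values="avg_tau").round(3))
```

prints (about 20 s on one CPU):

```
network: 97 nodes, 136 edges
sweep: 216 values of D; 93.8% of nodes transitioned at D = 1.085
stable ranges: 17 total, 2 qualifying (>= 15 unique D)
  D in [0.010, 0.770]  upper-state count 0
  D in [0.775, 0.860]  upper-state count 2
signal       avg_ac  avg_sd  dom_eig  max_ac  max_sd
node_set
all           0.695   0.882    0.794   0.714   0.811
high_input    0.795   0.862    0.826   0.735   0.818
lower_state   0.681   0.888    0.794   0.714   0.811
```

Reading the output: the configuration-model draw keeps its largest connected
component (97 of 100 nodes). The sweep climbs `D` in steps of 0.005 until
94% of nodes sit in the upper well, passing through 17 stable ranges of
which two are long enough to score. Every early warning signal anticipates
the transitions well (`τ` ≈ 0.68–0.89); the five High Input sentinels —
chosen by network input score — match or beat monitoring all 97 nodes,
which is the practical point: a handful of well-chosen nodes suffices.

The same pipeline is available from the shell:

```sh
netews generate --model powerlaw --n 100 --seed 42 --out net.edgelist
netews sweep --network net.edgelist --seed 42 --outdir sweep/
netews score --sweep-dir sweep/ --outdir scores/
```

`scores/tau.csv` then holds the tidy per-range τ table, and
`scores/per_transition_tau.csv` the τ of the stable range preceding each
transition.

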