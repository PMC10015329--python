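# Methods

## Model

The package simulates coupled double-well dynamics on an undirected,
unweighted network of `N` nodes,

    dx_i/dt = -(x_i - r1)(x_i - r2)(x_i - r3) + D Σ_j a_ij x_j + u + s ξ_i,

where the cubic term is the negative gradient of a quartic double-well
potential with stable wells near `r1` and `r3` and an unstable equilibrium
at `r2`; `D ≥ 0` couples each node diffusively to the *states* (not the
deviations) of its neighbours, `u` is a uniform additive stressor and
`s ξ_i` is independent Gaussian white noise per node. Because the coupling
aggregates raw neighbour states, high-degree nodes receive a large positive
input and lose their lower well first as `D` grows — the origin of the
staircase-like multi-stage transition on heterogeneous networks.

`s ξ_i` is interpreted as the formal derivative of a Wiener process scaled
by `s`, i.e. the model is an SDE integrated with the Euler–Maruyama scheme:
`x ← x + f(x) Δt + s √Δt Z` with `Z ~ N(0, 1)` i.i.d. per node per step,
drawn in node order from one seeded stream per simulation. The step is
fixed (`Δt = 0.01` TU by default); no adaptive integration is attempted so
that results are exactly reproducible from the seed and directly comparable
across parameter values.

### Macro states

Node states are classified against the critical points of the uncoupled
cubic, the two real roots of `d/dx[-(x-r1)(x-r2)(x-r3)] = 0`:

    x± = [(r1+r2+r3) ± √((r1+r2+r3)² − 3(r1r2+r1r3+r2r3))] / 3.

For the default `(1, 4, 7)` these are `4 ∓ √3 ≈ 2.268` and `5.732`. The
smaller root bounds the lower well's basin and classifies lower-start
sweeps; the larger root is used for upper-start sweeps. The boundary value
itself is assigned to the upper state (lower is defined by a strict `<`);
the boundary has measure zero, so the convention only matters for
degenerate inputs.

## Sweep protocol

The bifurcation parameter (`D` by default, optionally `u`) is swept
quasi-statically. At every value the state is reset to the starting well
(`x_i = r1` for lower start; `x_i = r3`, conventionally with `u = -15`, for
upper start), relaxed for 50 TU, then sampled `M = 250` times at 0.1 TU
intervals over 25 TU, so samples are taken from a stationary fluctuation
regime and no detrending is needed. Each parameter value gets an
independent noise stream spawned deterministically from the sweep seed and
the block index, which makes truncating the sweep (e.g. lowering the
stopping fraction) leave earlier blocks bit-identical. The sweep stops at
the first value where more than 90% of nodes have left the starting state;
sweeping `D` upward in steps of 0.005 from 0.01 this takes roughly 200
values on the default networks.

A node's *equilibrium* macro state at a parameter value is classified from
its mean over the `M` samples, which is robust to noise jitter around the
threshold. The instant the protocol does not pin down is which snapshot
defines node-set membership; we use the instantaneous state at the end of
relaxation (t = 50 TU), and both choices agree except in the rare blocks
where a node switches wells during the sampling window.

*Stable ranges* are maximal runs of consecutive parameter values with a
constant upper-state count. The terminal block — the one crossing the
stopping fraction — is excluded from range membership: it marks the final
transition rather than a point of any stable regime. A range qualifies for
scoring when it spans at least 15 unique parameter values.

## Early warning signals

From the `(M × k)` sample matrix of a node set, three statistics:

- dominant eigenvalue `λ_max` of the `k × k` sample covariance matrix
  (denominator `M - 1`; symmetric eigensolver; round-off negatives clamped
  to 0);
- per-node sample standard deviation (denominator `M - 1`);
- per-node lag-1 autocorrelation, `Σ_{m<M} (x_m - x̄)(x_{m+1} - x̄) / Σ_m
  (x_m - x̄)²` with the shared full-sample mean — the estimator whose
  denominator runs over all `M` terms, so it is slightly shrunk relative to
  the usual AR(1) fit but bounded in [-1, 1].

Aggregating the two per-node statistics by maximum and mean gives five
signals per node set: `dom_eig`, `max_sd`, `avg_sd`, `max_ac`, `avg_ac`.
A constant series has undefined autocorrelation and is excluded from the
AC aggregates rather than contributing a fabricated 0; an empty node set
yields all-missing signals, and missing values propagate to scoring, where
they are skipped.

## Sentinel node sets

Nine selection rules, re-applied at every parameter value (`n = 5` for the
fixed-size rules; ranking ties broken by lowest node index for
determinism):

| kind | rule |
|---|---|
| `all` | every node |
| `lower_state` / `upper_state` | nodes in that state at t = 50 TU |
| `high_input` / `low_input` | top / bottom `n` available nodes by `R_i = Σ_j a_ij x̄_j` |
| `lower_half` | available lower-state nodes with `R_i` strictly below the median of that candidate set |
| `random` | `n` nodes uniformly without replacement from all nodes |
| `large_correlation` | top `n` available nodes by `R'_i = Σ_{j≠i} cor(x_i, x_j) x̄_j` |
| `large_sd` | top `n` available nodes by sample s.d. |

An *available* node is one still in its original macro state. Two rules
leave room for interpretation and are implemented as explicit defaults:
`large_correlation` and `large_sd` are restricted to available nodes
(they are stand-ins for `high_input`, which is availability-restricted by
definition), while `random` draws from all nodes. Pairs involving a
constant series contribute 0 to `R'_i` (their correlation is undefined;
note that a naive `corrcoef` call would instead correlate rounding
residuals of constant series, so constancy is detected explicitly). A
reduced-sampling variant computes all membership scores from only the
first `k` samples (`membership_samples`) while the signals still use all
`M`.

## Scoring

Within each qualifying stable range, the Kendall tau-b correlation between
the parameter and each signal is computed over the values where the signal
is defined (a range contributes only if at least 15 defined pairs remain),
then averaged across contributing ranges with equal weight. tau-b is used
for its tie correction: parameter values within a range are distinct by
construction, so the correction only ever acts on tied signal values. The
signed τ is reported as-is — for downward sweeps a strongly *negative* τ is
the success criterion. τ here is a performance score, not a hypothesis
test, so no multiple-testing correction is applied. A per-transition table
reports the τ of the stable range immediately preceding each census change
(including the terminal one), labelled with the transition's parameter
value and the number of switching nodes. The tidy per-range τ table
exported by `evaluation.tau_table` (network, node set, signal, range, τ,
average τ) is the input a cross-network mixed-effects analysis would
consume; that analysis itself is out of scope for this package.

## Synthetic networks and what the tests show

No empirical networks ship with the package; generators cover the three
model families used throughout: configuration-model graphs with a
truncated power-law degree sequence (default `N = 100`, exponent 3,
minimum degree 2 — a size where multi-stage transitions are clear and a
full sweep takes tens of seconds), Erdős–Rényi graphs, and planted-
partition (stochastic block model) graphs. Generators return the largest
connected component, since coupling is meaningless across components, so
the delivered node count can be slightly below `N`. Users with empirical
networks supply them as edge lists or GraphML.

The end-to-end checks run one lower-start sweep at default parameters on
one power-law draw (test seed 42, chosen as the conventional test seed
before the run was scored). They demonstrate that the pipeline reproduces
the expected phenomenology on that study system — all five signals with
average τ above 0.65 for the All / Lower State / High Input sets, and High
Input average autocorrelation above 0.7 before each scored transition.
They do not demonstrate robustness across network topologies, noise
levels, or the upper-start direction (all supported, none scored in CI),
nor performance on real data, where unmodelled features — weighted or
directed interactions, non-stationary forcing, measurement noise — may
degrade the signals. The average-τ distribution across seeds straddles
0.65 for the weakest combination (the All set with an autocorrelation
signal): single-seed values in the 0.64–0.72 range are typical, so a
reproduction at another seed can fall marginally below the round figure.

## Numerical notes

- Euler–Maruyama discretization biases fluctuation statistics slightly:
  linearized about the lower well the node is an Ornstein–Uhlenbeck process
  with rate `θ = |f'(r1)| = 18`, whose discretized stationary s.d. is
  `s/√(2θ - θ²Δt)` (≈ 5% above `s/√36` at `Δt = 0.01`) and whose lag-0.1
  autocorrelation is `(1 - θΔt)^10 ≈ 0.137` versus the continuous
  `e^{-1.8} ≈ 0.165`. The property tests account for these tolerances.
- Trends in τ, not absolute signal levels, carry the information, so this
  bias does not affect the scoring.
- Degree sequences with an odd sum are resampled; multi-edges and
  self-loops from stub matching are collapsed, which thins the largest
  hubs slightly relative to the target power law.
- A sweep that cannot terminate (e.g. a network whose nodes never tip in
  the swept range) raises a non-termination error after `max_values`
  parameter values rather than looping forever; integration divergence
  reports the offending step.
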