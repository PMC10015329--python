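"""Sentinel node-set selection rules.

Nine rules pick which nodes' fluctuations feed the early warning signals:

- ``all``: every node.
- ``lower_state`` / ``upper_state``: nodes in that macro state at the end of
  relaxation (t = relax_time); either may be empty.
- ``high_input`` / ``low_input``: the n available nodes with the largest /
  smallest input score R_i = sum_j a_ij x̄_j (requires the network).
- ``lower_half``: available lower-state nodes with R_i strictly below the
  median R_i of available lower-state nodes.
- ``random``: n nodes uniformly at random from all nodes.
- ``large_correlation``: the n available nodes with the largest
  correlation-based proxy R'_i = sum_{j≠i} cor(x_i, x_j) x̄_j, for use when
  the adjacency matrix is unknown.
- ``large_sd``: the n available nodes with the largest sample s.d.

An *available* node is one still in its original macro state, hence still
able to tip in the sweep's direction.  Membership is recomputed at every
bifurcation-parameter value.  Ranking ties are broken by lowest node index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import Network
from .sweep import SampleBlock

__all__ = [
    "NODE_SET_KINDS",
    "NodeSetSpec",
    "input_scores",
    "correlation_scores",
    "select_node_set",
]

NODE_SET_KINDS = (
    "all",
    "lower_state",
    "upper_state",
    "high_input",
    "low_input",
    "lower_half",
    "random",
    "large_correlation",
    "large_sd",
)

_NEEDS_NETWORK = frozenset({"high_input", "low_input", "lower_half"})


@dataclass(frozen=True)
class NodeSetSpec:
    """A selection rule plus its size ``n`` (for fixed-size kinds)."""

    kind: str
    n: int = 5

    def __post_init__(self) -> None:
        if self.kind not in NODE_SET_KINDS:
            raise ValueError(f"unknown node-set kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def input_scores(net: Network, means: np.ndarray) -> np.ndarray:
    """Input score R_i = sum_j a_ij x̄_j for every node."""
    means = np.asarray(means, dtype=float)
    if means.size != net.N:
        raise ValueError("means length must equal the node count")
    return net.adjacency @ means


def correlation_scores(
    block: SampleBlock | np.ndarray, membership_samples: int | None = None
) -> np.ndarray:
    """Correlation proxy R'_i = sum_{j != i} cor(x_i, x_j) x̄_j.

    Pearson correlations are computed over the samples; pairs involving a
    constant series contribute 0.  ``membership_samples`` restricts the
    computation to the first k samples (reduced-sampling variant).
    """
    samples = block.samples if isinstance(block, SampleBlock) else np.asarray(block, float)
    if membership_samples is not None:
        samples = samples[:membership_samples]
    if samples.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation scores")
    means = samples.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(samples, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    # a constant series has no defined correlation with anything; corrcoef
    # would otherwise correlate its rounding residuals, so zero it explicitly
    constant = np.ptp(samples, axis=0) == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return corr @ means


def _top_n(scores: np.ndarray, candidates: np.ndarray, n: int, largest: bool) -> np.ndarray:
    """Top/bottom n of ``candidates`` by score; ties to the lowest index."""
    if candidates.size == 0:
        return candidates
    key = -scores[candidates] if largest else scores[candidates]
    order = candidates[np.argsort(key, kind="stable")]
    return np.sort(order[: min(n, candidates.size)])


def select_node_set(
    spec: NodeSetSpec,
    block: SampleBlock,
    net: Network | None = None,
    initial_side: str = "lower",
    threshold: float | None = None,
    rng: np.random.Generator | None = None,
    membership_samples: int | None = None,
) -> np.ndarray:
    """Apply one selection rule to a sample block; returns sorted indices.

    Macro-state membership uses the instantaneous state at t = relax_time
    against ``threshold`` (defaults to the block's own threshold).  If fewer
    than ``spec.n`` candidates are available, all candidates are returned.
    ``rng`` is required for the ``random`` kind.
    """
    if spec.kind in _NEEDS_NETWORK and net is None:
        raise ValueError(f"node-set kind {spec.kind!r} requires the network structure")
    if threshold is None:
        threshold = block.threshold
    samples = block.samples
    if membership_samples is not None:
        samples = samples[:membership_samples]
    means = samples.mean(axis=0)
    n_nodes = block.N
    lower_mask = block.state_at_relax < threshold
    available = lower_mask if initial_side == "lower" else ~lower_mask
    avail_idx = np.flatnonzero(available)

    kind = spec.kind
    if kind == "all":
        return np.arange(n_nodes)
    if kind == "lower_state":
        return np.flatnonzero(lower_mask)
    if kind == "upper_state":
        return np.flatnonzero(~lower_mask)
    if kind == "high_input":
        return _top_n(input_scores(net, means), avail_idx, spec.n, largest=True)
    if kind == "low_input":
        return _top_n(input_scores(net, means), avail_idx, spec.n, largest=False)
    if kind == "lower_half":
        cand = np.flatnonzero(lower_mask & available)
        if cand.size == 0:
            return cand
        r = input_scores(net, means)
        return cand[r[cand] < np.median(r[cand])]
    if kind == "random":
        if rng is None:
            raise ValueError("the random node set needs an rng")
        return np.sort(rng.choice(n_nodes, size=min(spec.n, n_nodes), replace=False))
    if kind == "large_correlation":
        return _top_n(correlation_scores(samples), avail_idx, spec.n, largest=True)
    if kind == "large_sd":
        sds = samples.std(axis=0, ddof=1)
        return _top_n(sds, avail_idx, spec.n, largest=True)
    raise ValueError(f"unknown node-set kind {kind!r}")  # pragma: no cover
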