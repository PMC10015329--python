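"""Quasi-static bifurcation sweep over the coupling strength or stressor.

At each value of the bifurcation parameter the system is re-started from the
initial condition, relaxed for ``relax_time`` TU, then sampled ``M`` times at
``sample_interval`` TU over ``sample_window`` TU.  Nodes are classified into
lower/upper macro states; the sweep stops once more than ``stop_fraction`` of
nodes have left their starting state.  Maximal runs of parameter values with
a constant macro-state census are the *stable ranges* on which early warning
signals are later scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .dynamics import DoubleWellParams, IntegrationDivergedError, classification_thresholds
from .network_io import Network

__all__ = [
    "SweepConfig",
    "SampleBlock",
    "SweepResult",
    "StableRange",
    "NonTerminationError",
    "run_sweep",
    "find_stable_ranges",
]


class NonTerminationError(RuntimeError):
    """The sweep exhausted ``max_values`` parameter values without the
    transitioned fraction ever exceeding ``stop_fraction``."""


@dataclass(frozen=True)
class SweepConfig:
    """Sweep protocol parameters.

    Defaults follow the standard protocol: lower start with the coupling
    strength D swept up from 0.01 in steps of 0.005, Euler–Maruyama step
    dt = 0.01, 50 TU relaxation, M = 250 samples at 0.1 TU spacing over
    25 TU, stopping once >90% of nodes have transitioned.
    """

    bif_param: str = "D"
    start: float = 0.01
    step: float = 0.005
    relax_time: float = 50.0
    sample_window: float = 25.0
    sample_interval: float = 0.1
    dt: float = 0.01
    stop_fraction: float = 0.9
    initial_side: str = "lower"
    n_sentinel: int = 5
    membership_samples: int | None = None
    max_values: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bif_param not in ("D", "u"):
            raise ValueError("bif_param must be 'D' or 'u'")
        if self.initial_side not in ("lower", "upper"):
            raise ValueError("initial_side must be 'lower' or 'upper'")
        if self.step == 0:
            raise ValueError("step must be non-zero")
        if not 0 < self.stop_fraction <= 1:
            raise ValueError("stop_fraction must be in (0, 1]")
        if self.M < 2:
            raise ValueError("need at least 2 samples per block")
        if self.membership_samples is not None and not 2 <= self.membership_samples <= self.M:
            raise ValueError("membership_samples must be in [2, M]")
        steps_per_sample = self.sample_interval / self.dt
        if abs(steps_per_sample - round(steps_per_sample)) > 1e-9:
            raise ValueError("sample_interval must be a multiple of dt")
        relax_steps = self.relax_time / self.dt
        if abs(relax_steps - round(relax_steps)) > 1e-9:
            raise ValueError("relax_time must be a multiple of dt")

    @property
    def M(self) -> int:
        """Number of samples per parameter value (sample_window / sample_interval)."""
        return round(self.sample_window / self.sample_interval)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        return cls(**d)


@dataclass(frozen=True)
class SampleBlock:
    """All samples taken at one bifurcation-parameter value.

    ``samples`` has shape (M, N) with ``samples[m-1, i] = x_i(relax_time +
    sample_interval * m)``; ``state_at_relax`` is the instantaneous state at
    t = relax_time (used for macro-state membership of node sets);
    ``upper_count`` counts nodes whose sample mean exceeds the threshold.
    """

    param_value: float
    sample_times: np.ndarray
    samples: np.ndarray
    state_at_relax: np.ndarray
    threshold: float
    is_terminal: bool = False

    @property
    def M(self) -> int:
        return self.samples.shape[0]

    @property
    def N(self) -> int:
        return self.samples.shape[1]

    @property
    def means(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sds(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1)

    @property
    def upper_mask(self) -> np.ndarray:
        """Macro-state per node from the per-node sample mean (True = upper)."""
        return self.means >= self.threshold

    @property
    def upper_count(self) -> int:
        return int(self.upper_mask.sum())


@dataclass
class SweepResult:
    """Ordered sample blocks of one sweep plus the termination record."""

    blocks: list[SampleBlock]
    config: SweepConfig
    params: DoubleWellParams
    threshold: float
    terminated: bool
    termination_reason: str

    @property
    def param_values(self) -> np.ndarray:
        return np.array([b.param_value for b in self.blocks])

    @property
    def upper_counts(self) -> np.ndarray:
        return np.array([b.upper_count for b in self.blocks])

    @property
    def N(self) -> int:
        return self.blocks[0].N

    def save(self, outdir) -> None:
        """Write the sweep to a directory: meta.json + samples.npz."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "params": asdict(self.params),
            "threshold": self.threshold,
            "terminated": self.terminated,
            "termination_reason": self.termination_reason,
            "param_values": [b.param_value for b in self.blocks],
            "terminal": [b.is_terminal for b in self.blocks],
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for i, b in enumerate(self.blocks):
            arrays[f"samples_{i}"] = b.samples
            arrays[f"relax_{i}"] = b.state_at_relax
        np.savez_compressed(outdir / "samples.npz", **arrays)

    @classmethod
    def load(cls, outdir) -> "SweepResult":
        from pathlib import Path

        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        config = SweepConfig.from_dict(meta["config"])
        with np.load(outdir / "samples.npz") as data:
            blocks = []
            times = config.relax_time + config.sample_interval * np.arange(1, config.M + 1)
            for i, (pv, term) in enumerate(zip(meta["param_values"], meta["terminal"])):
                blocks.append(
                    SampleBlock(
                        param_value=pv,
                        sample_times=times,
                        samples=data[f"samples_{i}"],
                        state_at_relax=data[f"relax_{i}"],
                        threshold=meta["threshold"],
                        is_terminal=term,
                    )
                )
        return cls(
            blocks=blocks,
            config=config,
            params=DoubleWellParams(**meta["params"]),
            threshold=meta["threshold"],
            terminated=meta["terminated"],
            termination_reason=meta["termination_reason"],
        )


@dataclass(frozen=True)
class StableRange:
    """A maximal run of consecutive parameter values with constant census."""

    block_indices: tuple[int, ...]
    param_values: tuple[float, ...]
    upper_count: int
    qualifies: bool

    def __len__(self) -> int:
        return len(self.block_indices)


def _simulate_block(
    adj: np.ndarray,
    params: DoubleWellParams,
    x0: np.ndarray,
    config: SweepConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one block; return (state at relax_time, M x N sample matrix)."""
    dt = config.dt
    relax_steps = round(config.relax_time / dt)
    steps_per_sample = round(config.sample_interval / dt)
    M = config.M
    n = x0.size
    r1, r2, r3, D, u, s = params.r1, params.r2, params.r3, params.D, params.u, params.s
    sq = math.sqrt(dt)
    x = x0.copy()
    samples = np.empty((M, n))
    state_at_relax = None
    total_steps = relax_steps + M * steps_per_sample
    next_sample_step = relax_steps + steps_per_sample
    m = 0
    for k in range(1, total_steps + 1):
        f = -(x - r1) * (x - r2) * (x - r3) + u
        if D:
            f += D * (adj @ x)
        x = x + f * dt
        if s:
            x += s * sq * rng.standard_normal(n)
        if k == relax_steps:
            if not np.all(np.isfinite(x)):
                raise IntegrationDivergedError(k, k * dt)
            state_at_relax = x.copy()
        if k == next_sample_step:
            samples[m] = x
            m += 1
            next_sample_step += steps_per_sample
    if not np.all(np.isfinite(samples)):
        raise IntegrationDivergedError(total_steps, total_steps * dt)
    return state_at_relax, samples


def run_sweep(net: Network, params: DoubleWellParams, config: SweepConfig) -> SweepResult:
    """Run the quasi-static sweep.

    For each parameter value the state is reset to the well matching
    ``config.initial_side`` (r1 everywhere for a lower start, r3 for an upper
    start) and integrated afresh with an independent noise stream derived
    from ``config.seed`` and the block index.  The sweep ends at the first
    value where the fraction of transitioned nodes exceeds
    ``stop_fraction``; that block is retained and flagged terminal.
    """
    lo, hi = classification_thresholds(params.r1, params.r2, params.r3)
    lower_start = config.initial_side == "lower"
    threshold = lo if lower_start else hi
    x0 = np.full(net.N, params.r1 if lower_start else params.r3)
    times = config.relax_time + config.sample_interval * np.arange(1, config.M + 1)
    adj = net.adjacency
    blocks: list[SampleBlock] = []
    for k in range(config.max_values):
        value = config.start + k * config.step
        if config.bif_param == "D":
            if value < 0:
                raise NonTerminationError(
                    f"coupling strength reached {value:g} < 0 before "
                    f"{config.stop_fraction:.0%} of nodes transitioned"
                )
            p = params.with_(D=value)
        else:
            p = params.with_(u=value)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        state_at_relax, samples = _simulate_block(adj, p, x0, config, rng)
        block = SampleBlock(
            param_value=value,
            sample_times=times,
            samples=samples,
            state_at_relax=state_at_relax,
            threshold=threshold,
        )
        upper = block.upper_count
        transitioned = upper / net.N if lower_start else (net.N - upper) / net.N
        if transitioned > config.stop_fraction:
            blocks.append(
                SampleBlock(
                    param_value=value,
                    sample_times=times,
                    samples=samples,
                    state_at_relax=state_at_relax,
                    threshold=threshold,
                    is_terminal=True,
                )
            )
            reason = (
                f"{transitioned:.1%} of nodes transitioned at "
                f"{config.bif_param} = {value:g}"
            )
            return SweepResult(blocks, config, params, threshold, True, reason)
        blocks.append(block)
    raise NonTerminationError(
        f"swept {config.max_values} values of {config.bif_param} without "
        f"more than {config.stop_fraction:.0%} of nodes transitioning"
    )


def find_stable_ranges(result: SweepResult, min_len: int = 15) -> list[StableRange]:
    """Partition the sweep into maximal constant-census runs.

    The terminal block (the one that crossed ``stop_fraction``) marks the
    final transition and is excluded.  A range ``qualifies`` when it spans at
    least ``min_len`` unique parameter values, the requirement for Kendall-τ
    scoring.
    """
    if not result.blocks:
        raise ValueError("empty sweep result")
    ranges: list[StableRange] = []
    run_idx: list[int] = []
    run_count: int | None = None

    def flush() -> None:
        if run_idx:
            values = tuple(result.blocks[i].param_value for i in run_idx)
            ranges.append(
                StableRange(
                    block_indices=tuple(run_idx),
                    param_values=values,
                    upper_count=run_count,
                    qualifies=len(set(values)) >= min_len,
                )
            )

    for i, block in enumerate(result.blocks):
        if block.is_terminal:
            break
        c = block.upper_count
        if run_count is None or c == run_count:
            run_idx.append(i)
            run_count = c
        else:
            flush()
            run_idx = [i]
            run_count = c
    flush()
    return ranges
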