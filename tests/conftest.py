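import numpy as np
import pytest

from netews import DoubleWellParams, Network, SampleBlock, SweepConfig, SweepResult
from netews.dynamics import classification_thresholds

LOWER_THRESHOLD, UPPER_THRESHOLD = classification_thresholds(1, 4, 7)


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 1
    a[1, 2] = a[2, 1] = 1
    return Network(a)


@pytest.fixture
def two_path():
    """Single edge 0-1."""
    return Network(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def star5():
    """Star with center 0 and 4 leaves."""
    a = np.zeros((5, 5))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return Network(a)


def make_block(
    samples,
    param_value=0.1,
    state_at_relax=None,
    threshold=LOWER_THRESHOLD,
    is_terminal=False,
):
    """Build a SampleBlock from an (M, N) sample matrix for unit tests."""
    samples = np.asarray(samples, dtype=float)
    if state_at_relax is None:
        state_at_relax = samples[0]
    times = 50.0 + 0.1 * np.arange(1, samples.shape[0] + 1)
    return SampleBlock(
        param_value=param_value,
        sample_times=times,
        samples=samples,
        state_at_relax=np.asarray(state_at_relax, dtype=float),
        threshold=threshold,
        is_terminal=is_terminal,
    )


def make_census_sweep(census, start=0.01, step=0.005, terminal_count=None, M=4, seed=0):
    """Synthetic SweepResult whose blocks realise a given upper-state census.

    ``census`` is a sequence of upper-state counts, one per parameter value;
    each block gets N = max(census)+1 nodes pinned at 7 (upper) or 1 (lower)
    plus a tiny deterministic jitter so signals are defined.
    """
    n_nodes = max(max(census), terminal_count or 0) + 1
    rng = np.random.default_rng(seed)
    blocks = []
    counts = list(census) + ([terminal_count] if terminal_count is not None else [])
    for k, count in enumerate(counts):
        value = start + k * step
        base = np.where(np.arange(n_nodes) < count, 7.0, 1.0)
        samples = base + 0.01 * rng.standard_normal((M, n_nodes))
        blocks.append(
            make_block(
                samples,
                param_value=value,
                state_at_relax=base,
                is_terminal=terminal_count is not None and k == len(counts) - 1,
            )
        )
    config = SweepConfig(
        start=start, step=step, sample_window=M * 0.1, sample_interval=0.1, seed=seed
    )
    return SweepResult(
        blocks=blocks,
        config=config,
        params=DoubleWellParams(s=0.05),
        threshold=LOWER_THRESHOLD,
        terminated=terminal_count is not None,
        termination_reason="synthetic",
    )
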