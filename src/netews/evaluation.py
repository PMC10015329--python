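"""Score early warning signals by Kendall rank correlation within stable ranges.

Within each qualifying stable range (>= ``min_len`` unique parameter values
with a constant macro-state census) the Kendall tau-b correlation between
the bifurcation parameter and each signal is computed, then averaged across
ranges.  tau near 1 means the signal rose monotonically towards the next
transition; for decreasing-parameter sweeps a large negative tau plays the
same role and the sign is reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ews import SIGNAL_NAMES, compute_signals
from .network_io import Network
from .sentinels import NODE_SET_KINDS, NodeSetSpec, select_node_set
from .sweep import StableRange, SweepResult, find_stable_ranges

__all__ = [
    "TauReport",
    "kendall_tau",
    "signal_table",
    "score_sweep",
    "per_transition_tau",
    "tau_table",
    "run_ews_analysis",
]

DEFAULT_KINDS = NODE_SET_KINDS


def kendall_tau(xs, ys) -> float:
    """Kendall tau-b (tie-corrected) rank correlation; NaN if ``ys`` all tied."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have equal length")
    if xs.size < 2 or np.unique(xs).size < 2:
        raise ValueError("need at least 2 values with xs not all tied")
    res = stats.kendalltau(xs, ys, variant="b")
    return float(res.statistic)


def signal_table(
    result: SweepResult,
    net: Network | None = None,
    kinds=DEFAULT_KINDS,
    n: int | None = None,
    membership_samples: int | None = None,
) -> pd.DataFrame:
    """The five signals per node set at every parameter value of a sweep.

    Node-set membership is recomputed at every block.  The ``random`` set is
    redrawn per block from a stream derived from the sweep seed, so the
    whole table is reproducible from (sweep seed, inputs).  Columns:
    block_index, param_value, node_set, set_size, dom_eig, max_sd, avg_sd,
    max_ac, avg_ac.
    """
    config = result.config
    if n is None:
        n = config.n_sentinel
    if membership_samples is None:
        membership_samples = config.membership_samples
    rows = []
    for i, block in enumerate(result.blocks):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i, 7]))
        for kind in kinds:
            idx = select_node_set(
                NodeSetSpec(kind=kind, n=n),
                block,
                net=net,
                initial_side=config.initial_side,
                threshold=result.threshold,
                rng=rng,
                membership_samples=membership_samples,
            )
            sig = compute_signals(block, idx)
            rows.append(
                {
                    "block_index": i,
                    "param_value": block.param_value,
                    "node_set": kind,
                    "set_size": idx.size,
                    **sig.as_dict(),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TauReport:
    """Per-range and averaged Kendall tau for one (node set, signal) pair."""

    node_set: str
    signal: str
    range_ids: tuple[int, ...]
    taus: tuple[float, ...]
    avg_tau: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.taus:
            raise ValueError("a TauReport needs at least one contributing range")
        object.__setattr__(self, "avg_tau", float(np.mean(self.taus)))


def score_sweep(
    result: SweepResult,
    ranges: list[StableRange],
    signals: pd.DataFrame,
    min_len: int = 15,
) -> list[TauReport]:
    """Kendall tau per qualifying stable range, averaged per (set, signal).

    Within a range, (parameter, signal) pairs with a missing signal are
    dropped; the range contributes only if at least ``min_len`` defined
    pairs remain.  Pairs with no contributing range are absent from the
    report.
    """
    import logging

    reports: list[TauReport] = []
    qualifying = [(rid, r) for rid, r in enumerate(ranges) if r.qualifies]
    if not qualifying:
        logging.getLogger(__name__).warning(
            "no stable range has >= %d unique parameter values; nothing to score",
            min_len,
        )
        return reports
    by_set = dict(tuple(signals.groupby("node_set")))
    for kind in signals["node_set"].unique():
        sub = by_set[kind].set_index("block_index")
        for sig_name in SIGNAL_NAMES:
            rids, taus = [], []
            for rid, rng_ in qualifying:
                idx = [i for i in rng_.block_indices if i in sub.index]
                vals = sub.loc[idx, sig_name].to_numpy(dtype=float)
                pvs = sub.loc[idx, "param_value"].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                if ok.sum() < min_len:
                    continue
                taus.append(kendall_tau(pvs[ok], vals[ok]))
                rids.append(rid)
            if taus:
                reports.append(
                    TauReport(
                        node_set=kind,
                        signal=sig_name,
                        range_ids=tuple(rids),
                        taus=tuple(taus),
                    )
                )
    return reports


def per_transition_tau(
    result: SweepResult,
    ranges: list[StableRange],
    signals: pd.DataFrame,
    min_len: int = 15,
) -> pd.DataFrame:
    """Kendall tau in the stable range immediately preceding each transition.

    A transition is a change of the macro-state census: either the first
    parameter value of the next stable range or, for the final transition,
    the terminal block that crossed the stopping fraction.  Rows are emitted
    only for transitions preceded by a qualifying range with enough defined
    signal values.  Columns: transition_param, n_switched, node_set, signal,
    range_id, tau.
    """
    transitions = []  # (preceding range id, transition param, count change)
    for rid in range(len(ranges) - 1):
        nxt = ranges[rid + 1]
        transitions.append(
            (rid, nxt.param_values[0], nxt.upper_count - ranges[rid].upper_count)
        )
    if result.terminated and ranges:
        term = next(b for b in result.blocks if b.is_terminal)
        transitions.append(
            (len(ranges) - 1, term.param_value, term.upper_count - ranges[-1].upper_count)
        )
    rows = []
    by_set = dict(tuple(signals.groupby("node_set")))
    for rid, t_param, switched in transitions:
        rng_ = ranges[rid]
        if not rng_.qualifies:
            continue
        for kind, sub in by_set.items():
            sub = sub.set_index("block_index")
            idx = [i for i in rng_.block_indices if i in sub.index]
            for sig_name in SIGNAL_NAMES:
                vals = sub.loc[idx, sig_name].to_numpy(dtype=float)
                pvs = sub.loc[idx, "param_value"].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                if ok.sum() < min_len:
                    continue
                rows.append(
                    {
                        "transition_param": t_param,
                        "n_switched": abs(int(switched)),
                        "node_set": kind,
                        "signal": sig_name,
                        "range_id": rid,
                        "tau": kendall_tau(pvs[ok], vals[ok]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["transition_param", "n_switched", "node_set", "signal", "range_id", "tau"],
    )


def tau_table(reports: list[TauReport], ranges: list[StableRange]) -> pd.DataFrame:
    """Tidy per-range tau table (one row per set, signal, range) with avg_tau.

    This is the table an external mixed-effects analysis across networks and
    seeds would consume.
    """
    rows = []
    for rep in reports:
        for rid, tau in zip(rep.range_ids, rep.taus):
            r = ranges[rid]
            rows.append(
                {
                    "node_set": rep.node_set,
                    "signal": rep.signal,
                    "range_id": rid,
                    "range_start": r.param_values[0],
                    "range_end": r.param_values[-1],
                    "tau": tau,
                    "avg_tau": rep.avg_tau,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["node_set", "signal", "range_id", "range_start", "range_end", "tau", "avg_tau"],
    )


def run_ews_analysis(
    net: Network,
    params,
    config,
    kinds=DEFAULT_KINDS,
    min_len: int = 15,
) -> dict:
    """End-to-end pipeline: sweep, stable ranges, signals, tau scores.

    Returns a dict with keys ``result`` (SweepResult), ``ranges``,
    ``signals`` (DataFrame), ``reports`` (list of TauReport),
    ``tau`` (tidy DataFrame) and ``per_transition`` (DataFrame).
    """
    from .sweep import run_sweep

    result = run_sweep(net, params, config)
    ranges = find_stable_ranges(result, min_len=min_len)
    signals = signal_table(result, net=net, kinds=kinds)
    reports = score_sweep(result, ranges, signals, min_len=min_len)
    return {
        "result": result,
        "ranges": ranges,
        "signals": signals,
        "reports": reports,
        "tau": tau_table(reports, ranges),
        "per_transition": per_transition_tau(result, ranges, signals, min_len=min_len),
    }
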