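"""Early warning statistics computed from a block of stationary samples.

Three statistics are computed from the M samples at one parameter value —
per-node sample standard deviation, per-node lag-1 autocorrelation, and the
dominant eigenvalue of the node-set covariance matrix — and aggregated into
five signals per node set: dom_eig, max_sd, avg_sd, max_ac, avg_ac.
Critical slowing down raises all five as a bifurcation approaches.

Missing values (empty node set, zero-variance series) are represented as
NaN and propagate; they are never silently replaced by 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sweep import SampleBlock

__all__ = [
    "SignalVector",
    "SIGNAL_NAMES",
    "lag1_autocorrelation",
    "node_sd",
    "dominant_cov_eigenvalue",
    "compute_signals",
]

SIGNAL_NAMES = ("dom_eig", "max_sd", "avg_sd", "max_ac", "avg_ac")


@dataclass(frozen=True)
class SignalVector:
    """The five early warning signals for one node set at one parameter value."""

    dom_eig: float
    max_sd: float
    avg_sd: float
    max_ac: float
    avg_ac: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SIGNAL_NAMES}


def lag1_autocorrelation(series: np.ndarray) -> float:
    """Lag-1 autocorrelation of a stationary series.

    Estimator: sum over m = 1..M-1 of (x_m - x̄)(x_{m+1} - x̄), divided by
    the sum over all M of (x_m - x̄)², with the shared full-sample mean x̄.
    A constant series has no fluctuations to correlate and yields NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    d = x - x.mean()
    denom = np.dot(d, d)
    if denom == 0:
        return float("nan")
    return float(np.dot(d[:-1], d[1:]) / denom)


def _lag1_all(samples: np.ndarray) -> np.ndarray:
    """Vectorized lag-1 autocorrelation for each column of an (M, k) matrix."""
    d = samples - samples.mean(axis=0)
    denom = np.einsum("mk,mk->k", d, d)
    num = np.einsum("mk,mk->k", d[:-1], d[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def node_sd(series: np.ndarray) -> float:
    """Sample standard deviation (denominator M-1)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(x.std(ddof=1))


def dominant_cov_eigenvalue(samples: np.ndarray) -> float:
    """Largest eigenvalue of the (M-1)-normalized sample covariance matrix.

    ``samples`` is (M, k) restricted to the node set; returns NaN for an
    empty set.  The symmetric eigensolver is used and tiny negative
    round-off is clamped to 0.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    m, k = samples.shape
    if k == 0:
        return float("nan")
    if m < 2:
        raise ValueError("need at least 2 samples")
    cov = np.atleast_2d(np.cov(samples, rowvar=False, ddof=1))
    return max(0.0, float(np.linalg.eigvalsh(cov)[-1]))


def compute_signals(block: SampleBlock, node_set: np.ndarray) -> SignalVector:
    """The five signals for ``node_set`` (indices into 0..N-1) of a block.

    Nodes whose autocorrelation is undefined (constant series) are excluded
    from max_ac/avg_ac; an empty node set yields all-NaN signals.
    """
    idx = np.asarray(node_set, dtype=int)
    if idx.size == 0:
        nan = float("nan")
        return SignalVector(nan, nan, nan, nan, nan)
    sub = block.samples[:, idx]
    sds = sub.std(axis=0, ddof=1)
    acs = _lag1_all(sub)
    defined = acs[np.isfinite(acs)]
    if defined.size:
        max_ac, avg_ac = float(defined.max()), float(defined.mean())
    else:
        max_ac = avg_ac = float("nan")
    return SignalVector(
        dom_eig=dominant_cov_eigenvalue(sub),
        max_sd=float(sds.max()),
        avg_sd=float(sds.mean()),
        max_ac=max_ac,
        avg_ac=avg_ac,
    )
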