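"""Coupled double-well stochastic dynamics on a network.

Each node ``i`` obeys

    dx_i/dt = -(x_i - r1)(x_i - r2)(x_i - r3) + D * sum_j a_ij x_j + u + s xi_i

where the cubic term derives from a quartic double-well potential with stable
equilibria near ``r1`` (lower well) and ``r3`` (upper well) separated by the
unstable equilibrium ``r2``; ``D >= 0`` is the diffusive coupling strength,
``u`` a uniform additive stressor and ``s xi_i`` Gaussian white noise of
intensity ``s``.  Integration is Euler–Maruyama with a fixed step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .network_io import Network

__all__ = [
    "DoubleWellParams",
    "Trajectory",
    "IntegrationDivergedError",
    "drift",
    "integrate",
    "classification_thresholds",
    "classify_states",
]

LOWER, UPPER = "lower", "upper"


class IntegrationDivergedError(RuntimeError):
    """Raised when the Euler–Maruyama state becomes non-finite."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(f"non-finite state at step {step} (t = {time:g})")


@dataclass(frozen=True)
class DoubleWellParams:
    """Constants of the double-well model.

    ``r1 < r2 < r3`` locate the equilibria (defaults 1, 4, 7); ``D`` is the
    coupling strength, ``u`` the stressor and ``s`` the noise intensity.
    """

    r1: float = 1.0
    r2: float = 4.0
    r3: float = 7.0
    D: float = 0.0
    u: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if not self.r1 < self.r2 < self.r3:
            raise ValueError("equilibrium locations must satisfy r1 < r2 < r3")
        if self.D < 0:
            raise ValueError("coupling strength D must be non-negative")
        if self.s < 0:
            raise ValueError("noise intensity s must be non-negative")

    def with_(self, **kwargs) -> "DoubleWellParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """A sampled path: ``times`` of shape (T,), ``states`` of shape (T, N)."""

    times: np.ndarray
    states: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path) -> None:
        import pandas as pd

        n = self.states.shape[1]
        df = pd.DataFrame(self.states, columns=[f"node_{i}" for i in range(n)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def drift(x: np.ndarray, net: Network | None, params: DoubleWellParams) -> np.ndarray:
    """Deterministic part of dx/dt: cubic well term + coupling + stressor."""
    x = np.asarray(x, dtype=float)
    if net is not None and x.shape[-1] != net.N:
        raise ValueError(f"state vector has length {x.shape[-1]}, network has {net.N} nodes")
    cubic = -(x - params.r1) * (x - params.r2) * (x - params.r3)
    coupling = params.D * (net.adjacency @ x) if net is not None else 0.0
    return cubic + coupling + params.u


def integrate(
    net: Network | None,
    params: DoubleWellParams,
    x0: float | np.ndarray,
    duration: float,
    dt: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Euler–Maruyama integration over ``duration`` time units.

    The update is ``x <- x + drift(x) dt + s sqrt(dt) Z`` with ``Z`` i.i.d.
    standard normal per node per step, drawn in node order from a single
    stream, so a given ``seed`` reproduces the trajectory exactly.  ``net``
    may be None for isolated (uncoupled) nodes, in which case ``x0`` fixes
    the dimension.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = round(duration / dt)
    if n_steps < 1 or abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be a positive multiple of dt")
    n = net.N if net is not None else np.atleast_1d(np.asarray(x0, float)).size
    x = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    states = np.empty((n_steps + 1, n))
    states[0] = x
    sqdt = math.sqrt(dt)
    adj = net.adjacency if net is not None else None
    r1, r2, r3, D, u, s = (
        params.r1, params.r2, params.r3, params.D, params.u, params.s,
    )
    for k in range(1, n_steps + 1):
        f = -(x - r1) * (x - r2) * (x - r3) + u
        if adj is not None and D:
            f += D * (adj @ x)
        x = x + f * dt
        if s:
            x += s * sqdt * rng.standard_normal(n)
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(k, k * dt)
        states[k] = x
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, states=states)


def classification_thresholds(r1: float, r2: float, r3: float) -> tuple[float, float]:
    """Critical points of the cubic well term, used as macro-state thresholds.

    These are the two real roots of ``d/dx [-(x-r1)(x-r2)(x-r3)] = 0``:

        x = [(r1+r2+r3) ± sqrt((r1+r2+r3)^2 - 3(r1 r2 + r1 r3 + r2 r3))] / 3

    returned ascending.  The smaller root bounds the lower well's basin (for
    defaults (1, 4, 7) it is 4 - sqrt(3) ≈ 2.268) and the larger root bounds
    the upper well's (4 + sqrt(3) ≈ 5.732).
    """
    if not r1 < r2 < r3:
        raise ValueError("need r1 < r2 < r3")
    sigma = r1 + r2 + r3
    pairs = r1 * r2 + r1 * r3 + r2 * r3
    disc = sigma * sigma - 3 * pairs
    assert disc > 0, "distinct ordered roots guarantee a positive discriminant"
    root = math.sqrt(disc)
    return ((sigma - root) / 3, (sigma + root) / 3)


def classify_states(x: np.ndarray, threshold: float) -> np.ndarray:
    """Label each node ``lower`` iff ``x_i < threshold``, else ``upper``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.where(np.asarray(x, dtype=float) < threshold, LOWER, UPPER)
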