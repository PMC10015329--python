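"""Independent brute-force oracles used by the test suite."""

import math

import numpy as np


def kendall_tau_b_brute(xs, ys):
    """Tie-corrected Kendall tau by explicit O(n^2) pair counting.

    tau_b = (C - D) / sqrt((n0 - tx)(n0 - ty)) with C/D the concordant and
    discordant pair counts, n0 = n(n-1)/2 and tx/ty the tied-pair counts in
    each variable.
    """
    xs = list(xs)
    ys = list(ys)
    n = len(xs)
    conc = disc = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = xs[i] - xs[j]
            dy = ys[i] - ys[j]
            if dx == 0 and dy == 0:
                tied_x += 1
                tied_y += 1
            elif dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tied_x) * (n0 - tied_y))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def ar1_series(phi, sigma, m, seed):
    """Exact stationary AR(1) sample path x_t = phi x_{t-1} + sigma eps_t."""
    rng = np.random.default_rng(seed)
    x = np.empty(m)
    x[0] = rng.normal(0, sigma / math.sqrt(1 - phi**2))
    eps = rng.normal(0, sigma, m)
    for t in range(1, m):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def powerlaw_mle_exponent(degrees, k_min):
    """Continuous-approximation MLE for a discrete power-law tail exponent:
    alpha = 1 + n / sum(log(k / (k_min - 1/2))) over degrees >= k_min."""
    ks = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    return 1.0 + ks.size / np.log(ks / (k_min - 0.5)).sum()


def modularity(adjacency, communities):
    """Newman modularity Q = sum_c (e_c / m - (d_c / 2m)^2) from first principles."""
    a = np.asarray(adjacency, dtype=float)
    m = a.sum() / 2
    deg = a.sum(axis=1)
    q = 0.0
    for comm in communities:
        idx = np.asarray(sorted(comm), dtype=int)
        e_c = a[np.ix_(idx, idx)].sum() / 2
        d_c = deg[idx].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q
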