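"""Network container, model-network generators and file I/O.

All dynamics in this package run on undirected, unweighted simple graphs.
The :class:`Network` container stores a dense symmetric 0/1 adjacency matrix
with nodes labelled ``0..N-1``; generators return the largest connected
component of the sampled graph because the diffusive coupling term is
meaningless across components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "generate_powerlaw_config",
    "generate_er",
    "generate_planted_communities",
    "read_network",
    "write_network",
]


@dataclass(frozen=True)
class Network:
    """An undirected, unweighted simple graph on nodes ``0..N-1``.

    Parameters
    ----------
    adjacency
        ``(N, N)`` symmetric matrix with entries in {0, 1} and zero diagonal.
    communities
        Optional planted partition (tuple of frozensets of node indices),
        populated by :func:`generate_planted_communities`.
    """

    adjacency: np.ndarray
    communities: tuple[frozenset[int], ...] | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if a.shape[0] < 2:
            raise ValueError("a network needs at least 2 nodes")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1 (unweighted)")
        object.__setattr__(self, "adjacency", a.astype(np.float64))

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @classmethod
    def from_graph(cls, g: nx.Graph, communities=None) -> "Network":
        """Build a Network from a networkx graph, relabelling nodes 0..N-1.

        Nodes are ordered by their sorted original labels (numerically when
        every label parses as an integer, so file round-trips preserve the
        node order); the mapping is applied to ``communities`` if given (a
        sequence of node collections).
        """
        try:
            nodes = sorted(g.nodes(), key=lambda v: (0, int(v)))
        except (TypeError, ValueError):
            nodes = sorted(g.nodes(), key=str)
        index = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, v in g.edges():
            if u == v:
                continue
            a[index[u], index[v]] = 1.0
            a[index[v], index[u]] = 1.0
        comm = None
        if communities is not None:
            comm = tuple(
                frozenset(index[v] for v in c if v in index) for c in communities
            )
            comm = tuple(c for c in comm if c)
        return cls(a, communities=comm)

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


def _largest_component(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0:
        raise ValueError("generated graph is empty")
    if nx.is_connected(g):
        return g
    cc = max(nx.connected_components(g), key=len)
    logger.info(
        "graph disconnected: keeping largest component with %d of %d nodes",
        len(cc),
        g.number_of_nodes(),
    )
    return g.subgraph(cc).copy()


def generate_powerlaw_config(
    N: int, exponent: float = 3.0, min_degree: int = 2, seed: int | None = None
) -> Network:
    """Configuration-model graph with a truncated power-law degree sequence.

    Degrees are drawn from ``P(k) ∝ k^-exponent`` on ``[min_degree, N-1]``;
    an odd-sum sequence is resampled.  Multi-edges and self-loops produced by
    the stub-matching construction are removed, then the largest connected
    component is returned, so the final node count may be below ``N``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    if min_degree < 1:
        raise ValueError("min_degree must be at least 1")
    rng = np.random.default_rng(seed)
    ks = np.arange(min_degree, N)
    if ks.size == 0:
        raise ValueError("min_degree must be below N")
    probs = ks.astype(float) ** -exponent
    probs /= probs.sum()
    for _ in range(1000):
        degrees = rng.choice(ks, size=N, p=probs)
        if degrees.sum() % 2 == 0:
            break
    else:  # pragma: no cover - even sum almost surely found long before
        raise RuntimeError("could not sample an even-sum degree sequence")
    multi = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(multi)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return Network.from_graph(_largest_component(g))


def generate_er(N: int, mean_degree: float, seed: int | None = None) -> Network:
    """Erdős–Rényi ``G(N, p)`` with ``p = mean_degree / (N-1)``; largest component."""
    if N < 2:
        raise ValueError("N must be at least 2")
    p = mean_degree / (N - 1)
    if not 0 < p <= 1:
        raise ValueError("mean_degree must lie in (0, N-1]")
    g = nx.gnp_random_graph(N, p, seed=seed)
    return Network.from_graph(_largest_component(g))


def generate_planted_communities(
    N: int,
    blocks: int,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> Network:
    """Stochastic block model with equal-size planted communities.

    Requires ``p_out <= p_in`` so the partition is assortative (equality
    degenerates to an Erdős–Rényi graph with no community structure).
    Returns the largest connected component, with the (restricted) planted
    partition recorded on the result's ``communities`` attribute.
    """
    if blocks < 2:
        raise ValueError("blocks must be at least 2")
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1 for a planted community structure")
    base, extra = divmod(N, blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(blocks)]
    if min(sizes) < 1:
        raise ValueError("more blocks than nodes")
    g = nx.stochastic_block_model(sizes, np.full((blocks, blocks), p_out) + np.eye(blocks) * (p_in - p_out), seed=seed)
    partition = [set(c) for c in g.graph["partition"]]
    g = _largest_component(g)
    return Network.from_graph(g, communities=partition)


def _read_edgelist(path: Path) -> nx.Graph:
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node labels, got {line!r}")
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dup += 1
            g.add_edge(u, v)
    if n_self or n_dup:
        logger.warning(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, n_self, n_dup
        )
    return g


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("edgelist", "graphml"):
            raise ValueError(f"unknown network format {format!r}")
        return format
    return "graphml" if path.suffix.lower() == ".graphml" else "edgelist"


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read a network from an edge-list or GraphML file.

    Directed input edges are symmetrized; duplicate edges and self-loops are
    dropped with a logged warning.  Arbitrary node labels are mapped to
    ``0..N-1`` in sorted-label order.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        g = nx.Graph(nx.read_graphml(path))
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("%s: dropped %d self-loop(s)", path, len(loops))
            g.remove_edges_from(loops)
    else:
        g = _read_edgelist(path)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph")
    return Network.from_graph(g)


def write_network(net: Network, path: str | Path, format: str | None = None) -> None:
    """Write a network as an edge list (``i j`` per line) or GraphML."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        with open(path, "w") as fh:
            fh.write(f"# {net.N} nodes, {net.n_edges} edges\n")
            rows, cols = np.nonzero(np.triu(net.adjacency))
            for u, v in zip(rows, cols):
                fh.write(f"{u} {v}\n")
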