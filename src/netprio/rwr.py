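"""Random walk with restart (RWR) network propagation.

A walker started at seed node n_i moves to a uniformly chosen neighbor with
probability 1 - r and restarts at n_i with probability r. The fixed point of

    q_{t+1} = (1 - r) W q_t + r s_{n_i}

is the steady-state visiting distribution and measures proximity of every
node to the seed. W is the column-stochastic, degree-normalized transition
operator; isolated nodes self-loop so probability mass is conserved.

The converged vectors, stacked seed-by-seed, form the proximity matrix used
as the Bayes-factor kernel in gene prioritization: entry (i, j) is the
steady-state probability of node j for a walk restarting at node i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "RWRConfig",
    "TransitionMatrix",
    "build_transition_matrix",
    "rwr",
    "rwr_proximity_matrix",
    "ProximityMatrix",
]


@dataclass(frozen=True)
class RWRConfig:
    """RWR parameters.

    restart_prob : restart probability r, in (0, 1). Default 0.3.
    tol : convergence threshold on the squared L2 norm of the step
        ``|q_{t+1} - q_t|^2``. Default 1e-6.
    max_iter : iteration cap; exceeding it raises.
    """

    restart_prob: float = 0.3
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError("restart_prob must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition operator over a fixed node ordering."""

    node_order: list[str]
    matrix: sp.csr_matrix  # column j sums to 1
    index: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.node_order)


def build_transition_matrix(net: nx.Graph) -> TransitionMatrix:
    """Degree-normalize the adjacency matrix into a column-stochastic operator.

    Column j spreads unit mass uniformly over j's neighbors; an isolated
    node's column is the unit vector on itself (self-loop), so total
    probability is conserved for every start node.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = nx.adjacency_matrix(net, nodelist=nodes).astype(float).tocsc()
    deg = np.asarray(adj.sum(axis=0)).ravel()
    isolated = np.flatnonzero(deg == 0)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    w = (adj @ sp.diags(inv)).tolil()
    for i in isolated:
        w[i, i] = 1.0
    return TransitionMatrix(node_order=nodes, matrix=w.tocsr(), index=idx)


def rwr(tm: TransitionMatrix, seed: str, cfg: RWRConfig | None = None) -> np.ndarray:
    """Converged RWR probability vector for one seed node.

    Power iteration from q_0 = s until ``|q_{t+1} - q_t|^2 < tol``.

    Returns the probability vector aligned with ``tm.node_order``; entries
    are nonnegative and sum to 1.
    """
    cfg = cfg or RWRConfig()
    if seed not in tm.index:
        raise KeyError(f"seed node {seed!r} not in network")
    mat = rwr_proximity_matrix(tm, cfg, restrict_rows={seed})
    return mat.values[0]


@dataclass
class ProximityMatrix:
    """Stacked converged RWR vectors: row i is the walk restarting at row_nodes[i].

    Entry (i, j) is the steady-state probability of ``col_nodes[j]``; each row
    sums to 1 and the diagonal entry of a row (seed on itself) is >= r.
    """

    row_nodes: list[str]
    col_nodes: list[str]
    values: np.ndarray  # shape (len(row_nodes), len(col_nodes))
    _row_index: dict[str, int]
    _col_index: dict[str, int]

    def has_row(self, gene: str) -> bool:
        return gene in self._row_index

    def value(self, row_gene: str, col_gene: str) -> float:
        return float(self.values[self._row_index[row_gene], self._col_index[col_gene]])

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._row_index[gene]]

    def col_indices(self, genes: list[str]) -> np.ndarray:
        return np.array([self._col_index[g] for g in genes], dtype=int)


def rwr_proximity_matrix(
    tm: TransitionMatrix,
    cfg: RWRConfig | None = None,
    restrict_rows: set[str] | None = None,
) -> ProximityMatrix:
    """Run RWR from every requested seed simultaneously.

    All seed columns are iterated as one dense block (sparse matvec per
    step); iteration stops once every column's squared step norm is below
    ``cfg.tol``. Raises if any column fails to converge in ``max_iter``.
    """
    cfg = cfg or RWRConfig()
    if restrict_rows is None:
        seeds = list(tm.node_order)
    else:
        unknown = set(restrict_rows) - set(tm.index)
        if unknown:
            raise KeyError(f"restrict_rows not in network: {sorted(unknown)[:5]}")
        seeds = sorted(restrict_rows)
    r = cfg.restart_prob
    n, k = tm.n, len(seeds)
    s = np.zeros((n, k))
    for j, node in enumerate(seeds):
        s[tm.index[node], j] = 1.0
    q = s.copy()
    w = tm.matrix
    for it in range(cfg.max_iter):
        q_next = (1.0 - r) * (w @ q) + r * s
        step = np.einsum("ij,ij->j", q_next - q, q_next - q)
        q = q_next
        if step.max() < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {cfg.max_iter} iterations "
            f"(max residual {step.max():.3e})"
        )
    return ProximityMatrix(
        row_nodes=seeds,
        col_nodes=list(tm.node_order),
        values=q.T.copy(),
        _row_index={g: i for i, g in enumerate(seeds)},
        _col_index=dict(tm.index),
    )
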