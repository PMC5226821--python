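"""Random Walk with Restart on the interaction network.

The walk iterates

    p[t+1] = (1 - lam) * M @ p[t] + lam * p0

where M is the column-normalized adjacency matrix, lam the restart
probability (default 0.5), and p0 assigns 1/k to each of the k seed nodes.
Iteration stops when the L1 difference between successive vectors falls
below ``tol`` (default 1e-6).  Because M is column-stochastic and p0 sums
to one, total probability is conserved at every step, and mass can never
leave the seeds' connected component(s).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import MissingNodeError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRConfig:
    """Restart probability, convergence tolerance (L1), and iteration cap."""

    restart_prob: float = 0.5
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over a fixed node ordering."""

    nodes: list[str]
    matrix: sp.csr_matrix
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}


@dataclass
class ProbabilityVector:
    """Stationary distribution of one walk, with convergence diagnostics."""

    nodes: list[str]
    probabilities: np.ndarray
    seeds: frozenset[str]
    iterations: int
    converged: bool

    def __getitem__(self, node: str) -> float:
        return float(self.probabilities[self.nodes.index(node)])


def build_transition_matrix(graph: nx.Graph) -> TransitionMatrix:
    """Column-normalize the adjacency matrix over a lexicographic node order.

    Requires a preprocessed network (no degree-0 nodes), otherwise a column
    would be all-zero and the matrix not stochastic.
    """
    nodes = sorted(graph.nodes())
    adjacency = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csc")
    degrees = np.asarray(adjacency.sum(axis=0)).ravel()
    if np.any(degrees == 0):
        raise AssertionError("degree-0 node in supposedly preprocessed network")
    normalized = adjacency @ sp.diags(1.0 / degrees)
    return TransitionMatrix(nodes=nodes, matrix=sp.csr_matrix(normalized))


def run_rwr(
    tm: TransitionMatrix, seeds: set[str] | frozenset[str], cfg: RWRConfig
) -> ProbabilityVector:
    """Iterate the walk from ``seeds`` to its stationary distribution."""
    if not seeds:
        raise ValueError("seed set must be non-empty")
    missing = [s for s in seeds if s not in tm.index]
    if missing:
        raise MissingNodeError(missing[0])

    n = len(tm.nodes)
    p0 = np.zeros(n)
    for seed in seeds:
        p0[tm.index[seed]] = 1.0 / len(seeds)

    lam = cfg.restart_prob
    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        p_next = (1.0 - lam) * (tm.matrix @ p) + lam * p0
        if np.abs(p_next - p).sum() < cfg.tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        warnings.warn(
            f"RWR did not converge within {cfg.max_iter} iterations",
            stacklevel=2,
        )
    return ProbabilityVector(
        nodes=tm.nodes,
        probabilities=p,
        seeds=frozenset(seeds),
        iterations=iterations,
        converged=converged,
    )


def top_candidates(pv: ProbabilityVector, k: int = 10) -> list[tuple[str, float]]:
    """The K non-seed nodes most accessible from the seeds.

    Seeds are excluded; ties broken lexicographically by gene id; nodes with
    zero probability (other components) never qualify, so fewer than K
    candidates may be returned.
    """
    ranked = sorted(
        (
            (node, float(p))
            for node, p in zip(pv.nodes, pv.probabilities)
            if node not in pv.seeds and p > 0.0
        ),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:k]
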