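"""Random Walk with Restart (RWR) on an interaction network.

The walker follows the update

    p(t+1) = (1 - r) * W^T p(t) + r * p0

where ``W`` is the row-normalized adjacency matrix (outgoing mass of node i
splits equally over its neighbours), ``r`` is the restart probability and
``p0`` is the restart vector: 1 for each seed, 0 otherwise. At the fixed
point the entries of ``p`` rank nodes by the steady-state flow they receive
from the seed set; this ranking is what connector pruning consumes. Because
``W`` is row-stochastic the iteration conserves total probability mass, and
only the ranking (which is invariant to scaling of ``p0``) matters
downstream, so ``p0`` is left unnormalized by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = ["RWRParams", "RWRResult", "restart_vector", "rwr_steady_state", "write_rwr_tsv"]


@dataclass(frozen=True)
class RWRParams:
    """Solver parameters.

    restart : probability of jumping back to the seed distribution at each
        step; default 0.75.
    tolerance : L1 convergence threshold on successive iterates.
    max_iterations : iteration cap; exceeding it sets ``converged=False``
        on the result rather than raising.
    normalize_restart : divide p0 by its sum (scales probabilities, not the
        ranking).
    weighted : row-normalize by edge weights instead of plain degree.
    """

    restart: float = 0.75
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    normalize_restart: bool = False
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart probability must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RWRResult:
    probabilities: dict[str, float]
    iterations_used: int
    converged: bool
    residual: float
    params: RWRParams = field(default_factory=RWRParams)

    def ranking(self) -> list[str]:
        """Nodes by descending probability, ties broken lexicographically."""
        return sorted(self.probabilities, key=lambda n: (-self.probabilities[n], n))


def restart_vector(net: nx.Graph, seeds: Iterable[str]) -> dict[str, float]:
    """Restart vector p0: 1.0 for every seed, 0.0 for every other node."""
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("seed set is empty")
    missing = seed_set - set(net.nodes)
    if missing:
        raise KeyError(f"seeds not in network: {sorted(missing)}")
    return {n: (1.0 if n in seed_set else 0.0) for n in net.nodes}


def rwr_steady_state(
    net: nx.Graph, seeds: Iterable[str], params: RWRParams | None = None
) -> RWRResult:
    """Iterate the RWR update to its fixed point.

    Equivalent to solving p = r (I - (1-r) W^T)^-1 p0 directly; the power
    iteration converges geometrically at rate (1 - r). Every node must have
    degree >= 1 (strip isolated nodes first: a dangling node would absorb
    walker mass and break row-stochasticity).
    """
    params = params or RWRParams()
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("empty network")
    isolated = [n for n in nodes if net.degree(n) == 0]
    if isolated:
        raise ValueError(f"isolated nodes present (strip them first): {isolated[:5]}")

    idx = {n: i for i, n in enumerate(nodes)}
    weight = "weight" if params.weighted else None
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=weight, format="csr")
    adj = adj.astype(float)
    strength = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(strength <= 0):
        raise ValueError("non-positive node strength under the requested weighting")
    # W^T p = A D^-1 p for symmetric A.
    inv_deg = sparse.diags(1.0 / strength)
    trans = adj @ inv_deg

    p0 = np.zeros(len(nodes))
    for s in set(seeds):
        if s not in idx:
            raise KeyError(f"seed {s!r} not in network")
        p0[idx[s]] = 1.0
    if not p0.any():
        raise ValueError("seed set is empty")
    if params.normalize_restart:
        p0 = p0 / p0.sum()

    r = params.restart
    p = p0.copy()
    converged = False
    residual = np.inf
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        p_next = (1.0 - r) * (trans @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < params.tolerance:
            converged = True
            break
    return RWRResult(
        probabilities={n: float(p[idx[n]]) for n in nodes},
        iterations_used=iterations,
        converged=converged,
        residual=residual,
        params=params,
    )


def write_rwr_tsv(result: RWRResult, path: str | Path) -> None:
    """Dump the steady-state vector as (node, probability), descending."""
    with open(path, "w") as fh:
        fh.write("node\tprobability\n")
        for n in result.ranking():
            fh.write(f"{n}\t{result.probabilities[n]:.12g}\n")
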