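"""Independent reference implementations used as test oracles.

Each function here re-derives a result by the most literal route available
(dense linear algebra, exhaustive enumeration, unoptimized loops) and is
deliberately kept separate from the library code paths it checks.
"""

from __future__ import annotations

import itertools
from itertools import combinations

import networkx as nx
import numpy as np


def random_connected_graph(rng: np.random.Generator, max_nodes: int, p: float | None = None) -> nx.Graph:
    """Seeded Erdős–Rényi graph, resampled until connected."""
    n = int(rng.integers(3, max_nodes + 1))
    p = p if p is not None else min(1.0, 2.5 / n + 0.1)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def rwr_dense_solve(net: nx.Graph, seeds: set[str], r: float = 0.75) -> dict[str, float]:
    """Direct solve of p = r (I - (1-r) W^T)^-1 p0 with dense linear algebra."""
    nodes = sorted(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes)
    w = a / a.sum(axis=1, keepdims=True)
    p0 = np.array([1.0 if n in seeds else 0.0 for n in nodes])
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1.0 - r) * w.T, p0)
    return dict(zip(nodes, p))


def pool_bruteforce(net: nx.Graph, seeds: set[str], d: int, strict: bool = True) -> set[str]:
    """Candidate pool by explicit enumeration of bounded seed-seed paths."""
    budget = d + 1
    out: set[str] = set()
    for s, t in combinations(sorted(seeds), 2):
        if not nx.has_path(net, s, t):
            continue
        if strict:
            if nx.shortest_path_length(net, s, t) > budget:
                continue
            for path in nx.all_shortest_paths(net, s, t):
                out.update(path[1:-1])
        else:
            ds = nx.single_source_shortest_path_length(net, s)
            dt = nx.single_source_shortest_path_length(net, t)
            for v in net.nodes:
                if v != s and v != t and v in ds and v in dt and ds[v] + dt[v] <= budget:
                    out.add(v)
    return out - set(seeds)


def prune_reference(seeds: set[str], ranked: list[str], net: nx.Graph) -> nx.Graph:
    """Literal single-pass pruning: copy the graph at every step."""
    gs = net.subgraph(set(seeds) | set(ranked)).copy()
    n_comp = nx.number_connected_components(gs)
    for cand in ranked:
        trial = gs.copy()
        trial.remove_node(cand)
        if nx.number_connected_components(trial) == n_comp:
            gs = trial
    return gs


def hypergeom_enumeration(k: int, ks: int, s: int, n_nodes: int) -> float:
    """P(links to seeds >= ks) by enumerating every k-subset of the N-1
    possible neighbours, s of which are seeds."""
    others = range(n_nodes - 1)
    hits = total = 0
    for combo in itertools.combinations(others, k):
        total += 1
        if sum(1 for x in combo if x < s) >= ks:
            hits += 1
    return hits / total if total else 1.0


def bh_stepup_reference(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini–Hochberg step-up, written from the definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, pvalues[i] * n / rank_from_end)
        adjusted[i] = running_min
    return adjusted


def sca_greedy_reference(net: nx.Graph, seeds: set[str]) -> set[str]:
    """Literal greedy LCC growth over the fixed first-neighbour pool;
    returns the final member set (before largest-component extraction)."""
    seeds = set(seeds) & set(net.nodes)
    pool = {v for u in seeds for v in net.neighbors(u)} - seeds

    def lcc_size(nodes: set[str]) -> int:
        sub = net.subgraph(nodes)
        return max((len(c) for c in nx.connected_components(sub)), default=0)

    current = set(seeds)
    size = lcc_size(current)
    while True:
        best = None
        for cand in sorted(pool - current):
            new_size = lcc_size(current | {cand})
            if new_size <= size:
                continue
            links = sum(1 for u in net.neighbors(cand) if u in current)
            key = (-new_size, -links, cand)
            if best is None or key < best[0]:
                best = (key, cand, new_size)
        if best is None:
            return current
        current.add(best[1])
        size = best[2]
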