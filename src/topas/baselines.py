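"""Bottom-up baseline module-detection methods: SCA, DIAMOnD and MaxLink.

All three grow a module outward from the seed genes:

* **DIAMOnD** iteratively adds, for a preset number of rounds (200 by
  default), the candidate whose connectivity to the current cluster is most
  significant under a hypergeometric test.
* **MaxLink** scores every first neighbour of the seeds by its number of
  links to them and keeps those whose link count is significant
  (hypergeometric p < alpha).
* **SCA** (Seed Connector Algorithm) greedily adds, from the fixed pool of
  first neighbours of the seeds, the connector that most increases the size
  of the largest connected component of the growing subnetwork, stopping
  when no candidate helps.

For evaluation parity with TOPAS, only the largest connected component of
each prediction is taken into account (``extract_largest_module``).

The shared hypergeometric universe excludes the evaluated node itself:
its k neighbours are drawn from the N-1 other nodes, s of which are seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable

import networkx as nx

from .core import Module
from .graph import induced_subgraph, largest_connected_component

__all__ = [
    "RankedAddition",
    "hypergeom_connectivity_pvalue",
    "extract_largest_module",
    "run_diamond",
    "run_maxlink",
    "run_sca",
]


@dataclass(frozen=True)
class RankedAddition:
    """One prioritized node: its 1-based addition rank, hypergeometric
    p-value (when applicable) and link count to the seeds/cluster."""

    node: str
    rank: int
    p_value: float | None
    links_to_seeds: int


def hypergeom_connectivity_pvalue(k: int, ks: int, s: int, n_nodes: int) -> float:
    """Upper-tail probability that a degree-k node has >= ks links to seeds.

    Exact integer arithmetic:  p = sum_{i=ks}^{min(k,s)} C(s,i) C(N-1-s,k-i)
    / C(N-1,k), with the universe of possible neighbours excluding the node
    itself (N-1 nodes, s of them seeds).
    """
    if not (0 <= ks <= min(k, s)):
        raise ValueError(f"need 0 <= ks <= min(k, s); got k={k}, ks={ks}, s={s}")
    if not (0 < s < n_nodes):
        raise ValueError(f"need 0 < s < N; got s={s}, N={n_nodes}")
    if k > n_nodes - 1:
        raise ValueError(f"degree k={k} exceeds N-1={n_nodes - 1}")
    if ks == 0:
        return 1.0
    universe = n_nodes - 1
    numer = sum(comb(s, i) * comb(universe - s, k - i) for i in range(ks, min(k, s) + 1))
    return numer / comb(universe, k)


def extract_largest_module(
    net: nx.Graph, seeds: Iterable[str], members: Iterable[str]
) -> Module:
    """Largest connected component of the subgraph induced by ``members``,
    partitioned into seeds and connectors. Shared by every method so that
    evaluation compares like with like."""
    seed_set = set(seeds)
    member_set = set(members) | (seed_set & set(net.nodes))
    sub = induced_subgraph(net, member_set)
    if sub.number_of_nodes() == 0:
        return Module(seeds=set(), connectors=set(), graph=nx.Graph())
    top = largest_connected_component(sub, sub.nodes)
    g = sub.subgraph(top).copy()
    return Module(seeds=set(g.nodes) & seed_set, connectors=set(g.nodes) - seed_set, graph=g)


def run_diamond(
    net: nx.Graph, seeds: Iterable[str], n_added: int = 200
) -> tuple[list[RankedAddition], Module]:
    """DIAMOnD: iterative hypergeometric expansion of the seed cluster.

    At each of ``n_added`` rounds every non-member neighbour of the current
    cluster is scored with :func:`hypergeom_connectivity_pvalue` (the cluster
    counts as the seed set), and the lowest-p node joins the cluster. Ties
    break on higher link count, lower degree, then node ID. Stops early if
    the cluster has no external neighbour.
    """
    if n_added < 1:
        raise ValueError("n_added must be >= 1")
    seed_set = set(seeds) & set(net.nodes)
    if not seed_set:
        raise ValueError("no seed present in the network")
    n_nodes = net.number_of_nodes()
    cluster = set(seed_set)
    additions: list[RankedAddition] = []
    for rank in range(1, n_added + 1):
        frontier = {v for c in cluster for v in net.neighbors(c)} - cluster
        if not frontier:
            break
        s = len(cluster)
        best = None
        for v in sorted(frontier):
            k = net.degree(v)
            ks = sum(1 for u in net.neighbors(v) if u in cluster)
            p = hypergeom_connectivity_pvalue(k, ks, s, n_nodes)
            key = (p, -ks, k, v)
            if best is None or key < best[0]:
                best = (key, v, p, ks)
        _, node, p, ks = best
        cluster.add(node)
        additions.append(RankedAddition(node=node, rank=rank, p_value=p, links_to_seeds=ks))
    module = extract_largest_module(net, seed_set, cluster)
    return additions, module


def run_maxlink(
    net: nx.Graph, seeds: Iterable[str], alpha: float = 0.05
) -> tuple[list[RankedAddition], Module]:
    """MaxLink: first-neighbour link-count test.

    Candidates are the non-seed first neighbours of the seeds; each is scored
    by its number of links to the seed set and retained when the
    hypergeometric p-value is below ``alpha``. Retained candidates are ranked
    by link count descending, then p ascending, then node ID.
    """
    seed_set = set(seeds) & set(net.nodes)
    if not seed_set:
        raise ValueError("no seed present in the network")
    n_nodes = net.number_of_nodes()
    s = len(seed_set)
    candidates = {v for u in seed_set for v in net.neighbors(u)} - seed_set
    scored = []
    for v in sorted(candidates):
        k = net.degree(v)
        ks = sum(1 for u in net.neighbors(v) if u in seed_set)
        p = hypergeom_connectivity_pvalue(k, ks, s, n_nodes)
        if p < alpha:
            scored.append((v, ks, p))
    scored.sort(key=lambda t: (-t[1], t[2], t[0]))
    additions = [
        RankedAddition(node=v, rank=i, p_value=p, links_to_seeds=ks)
        for i, (v, ks, p) in enumerate(scored, start=1)
    ]
    module = extract_largest_module(net, seed_set, seed_set | {a.node for a in additions})
    return additions, module


def run_sca(net: nx.Graph, seeds: Iterable[str]) -> Module:
    """SCA: greedy bottom-up growth of the seed LCC.

    The connector pool is fixed up front as all first neighbours of the
    seeds. Repeatedly add the pool member that maximally increases the LCC
    size of the growing subnetwork (ties: higher link count to the current
    subnetwork, then node ID); stop when no candidate increases it.
    """
    seed_set = set(seeds) & set(net.nodes)
    if not seed_set:
        raise ValueError("no seed present in the network")
    pool = {v for u in seed_set for v in net.neighbors(u)} - seed_set
    current = set(seed_set)
    lcc_size = len(largest_connected_component(net, current)) if current else 0
    while True:
        best = None
        for cand in sorted(pool - current):
            size = len(largest_connected_component(net, current | {cand}))
            if size <= lcc_size:
                continue
            links = sum(1 for u in net.neighbors(cand) if u in current)
            key = (-size, -links, cand)
            if best is None or key < best[0]:
                best = (key, cand, size)
        if best is None:
            break
        _, node, size = best
        current.add(node)
        lcc_size = size
    return extract_largest_module(net, seed_set, current)
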