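"""The TOPAS algorithm: top-down attachment of seeds.

Given seed genes and an interaction network, the method

1. restricts the network to its largest connected component (preprocessing),
2. collects every non-seed node lying on a bounded shortest path between two
   seeds into a candidate connector pool (``d`` = maximum number of
   intermediate connectors allowed between any seed pair, so the seed-seed
   hop bound is ``d + 1`` edges),
3. ranks candidates by their Random-Walk-with-Restart steady-state
   probability,
4. prunes the subnetwork induced by seeds plus candidates in a single pass,
   removing each candidate — lowest RWR flow first — whenever its removal
   leaves the number of connected components unchanged.

The surviving subnetwork is the predicted disease module: all seeds plus the
minimal set of high-flow connectors that keeps them as connected as the pool
allows. Pruning never alters the partition of seeds into connected
components, so seed recovery is decided entirely by the pool construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx

from .graph import (
    SeedSet,
    bfs_distances,
    connected_components,
    induced_subgraph,
    largest_connected_component,
)
from .rwr import RWRParams, RWRResult, rwr_steady_state

logger = logging.getLogger(__name__)

__all__ = [
    "TopasConfig",
    "CandidatePool",
    "Module",
    "preprocess",
    "build_candidate_pool",
    "rank_candidates",
    "prune",
    "run_topas",
]

MODULE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TopasConfig:
    """Configuration for a TOPAS run.

    d : maximum allowed connectors between any two seeds (1-3 recommended;
        larger values admit functionally unrelated genes and trigger a
        warning).
    rwr_params : parameters of the ranking random walk.
    on_shortest_paths_only : if True (default) a candidate must lie on an
        actual shortest seed-seed path of length <= d+1; if False it merely
        needs dist(s, v) + dist(v, t) <= d+1 for some seed pair.
    """

    d: int = 2
    rwr_params: RWRParams = field(default_factory=RWRParams)
    on_shortest_paths_only: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.d > 3:
            logger.warning("d=%d > 3: distant connectors may be functionally unrelated", self.d)


@dataclass
class CandidatePool:
    """Potential connectors between seeds, optionally ranked for pruning."""

    candidates: set[str]
    score: dict[str, float] = field(default_factory=dict)
    ranked: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class Module:
    """A predicted disease module: seeds + connectors and their edges."""

    seeds: set[str]
    connectors: set[str]
    graph: nx.Graph

    def __post_init__(self) -> None:
        if self.seeds & self.connectors:
            raise ValueError("seeds and connectors must be disjoint")
        if set(self.graph.nodes) != self.seeds | self.connectors:
            raise ValueError("module graph nodes must equal seeds + connectors")

    @property
    def nodes(self) -> set[str]:
        return self.seeds | self.connectors

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    @property
    def components(self) -> list[set[str]]:
        return connected_components(self.graph)

    def largest_component(self) -> "Module":
        """The largest predicted module (evaluation always scores this)."""
        if self.graph.number_of_nodes() == 0:
            return self
        top = self.components[0]
        return Module(
            seeds=self.seeds & top,
            connectors=self.connectors & top,
            graph=self.graph.subgraph(top).copy(),
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": MODULE_SCHEMA_VERSION,
            "seeds": sorted(self.seeds),
            "connectors": sorted(self.connectors),
            "edges": [list(e) for e in self.edges],
            "components": [sorted(c) for c in self.components],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "Module":
        g = nx.Graph()
        g.add_nodes_from(data["seeds"])
        g.add_nodes_from(data["connectors"])
        g.add_edges_from(tuple(e) for e in data["edges"])
        return cls(seeds=set(data["seeds"]), connectors=set(data["connectors"]), graph=g)

    @classmethod
    def from_json(cls, path: str | Path) -> "Module":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def write_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u}\t{v}\n")


def preprocess(net: nx.Graph, seeds: SeedSet | Iterable[str]) -> tuple[nx.Graph, set[str]]:
    """Restrict the network to its largest connected component.

    Seeds outside the component are logged and excluded: they cannot be
    joined to the main module and would otherwise distort the random walk.
    Returns the component subgraph and the connectable seed set.
    """
    mapped = set(seeds.mapped) if isinstance(seeds, SeedSet) else set(seeds) & set(net.nodes)
    if not mapped:
        raise ValueError("no mapped seed present in the network")
    lcc = largest_connected_component(net)
    connectable = mapped & set(lcc.nodes)
    excluded = mapped - connectable
    if excluded:
        logger.info("excluding %d seed(s) outside the network LCC: %s",
                    len(excluded), sorted(excluded))
    if not connectable:
        raise ValueError("no mapped seed lies in the largest network component")
    if isinstance(seeds, SeedSet):
        seeds.connectable = connectable
    return lcc, connectable


def build_candidate_pool(
    net: nx.Graph,
    seeds: Iterable[str],
    d: int,
    on_shortest_paths_only: bool = True,
) -> CandidatePool:
    """Collect potential seed connectors by truncated BFS from each seed.

    A non-seed node v enters the pool iff there are seeds s != t with
    dist(s,v) + dist(v,t) == dist(s,t) <= d+1 (v on a shortest path of at
    most d+1 edges, i.e. at most d intermediates). In the relaxed mode the
    condition is dist(s,v) + dist(v,t) <= d+1, admitting slight detours.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    seed_set = set(seeds)
    missing = seed_set - set(net.nodes)
    if missing:
        raise KeyError(f"seeds not in network: {sorted(missing)}")
    if len(seed_set) < 2:
        return CandidatePool(candidates=set())

    budget = d + 1
    dist = {s: bfs_distances(net, s, budget) for s in seed_set}
    candidates: set[str] = set()
    for s, t in combinations(sorted(seed_set), 2):
        ds, dt = dist[s], dist[t]
        d_st = ds.get(t)
        if on_shortest_paths_only:
            if d_st is None:  # farther apart than d+1 hops
                continue
            for v, dv in ds.items():
                if v in seed_set or v in candidates:
                    continue
                if dv + dt.get(v, budget + 1) == d_st:
                    candidates.add(v)
        else:
            for v, dv in ds.items():
                if v in seed_set or v in candidates:
                    continue
                if dv + dt.get(v, budget + 1) <= budget:
                    candidates.add(v)
    return CandidatePool(candidates=candidates)


def rank_candidates(pool: CandidatePool, rwr: RWRResult) -> CandidatePool:
    """Order candidates for pruning by ascending RWR steady-state probability.

    Low-flow candidates are tested (and typically removed) first, so the
    connectors carrying the highest walker flow survive. Ties break
    lexicographically on the node ID for reproducibility.
    """
    missing = pool.candidates - set(rwr.probabilities)
    if missing:
        raise KeyError(f"candidates missing from RWR vector: {sorted(missing)[:5]}")
    score = {c: rwr.probabilities[c] for c in pool.candidates}
    ranked = sorted(pool.candidates, key=lambda c: (score[c], c))
    return CandidatePool(candidates=set(pool.candidates), score=score, ranked=ranked)


def prune(seeds: Iterable[str], pool: CandidatePool, net: nx.Graph) -> Module:
    """Single-pass component-preserving pruning of the candidate subnetwork.

    Starting from G_s, the subgraph induced by seeds + candidates, each
    ranked candidate is tentatively deleted; the deletion becomes permanent
    iff the number of connected components of the remaining nodes is
    unchanged. After all candidates are tested the surviving subnetwork is
    the module; survivors are its connectors.
    """
    seed_set = set(seeds)
    g = induced_subgraph(net, seed_set | pool.candidates)
    order = pool.ranked if pool.ranked else sorted(pool.candidates)
    n_comp = nx.number_connected_components(g)
    for cand in order:
        if cand not in g:
            continue
        neighbors = list(g.neighbors(cand))
        g.remove_node(cand)
        if nx.number_connected_components(g) != n_comp:
            g.add_node(cand)
            g.add_edges_from((cand, u) for u in neighbors)
    connectors = set(g.nodes) - seed_set
    return Module(seeds=set(g.nodes) & seed_set, connectors=connectors, graph=g)


def run_topas(
    net: nx.Graph,
    seeds: SeedSet | Iterable[str],
    config: TopasConfig | None = None,
) -> Module:
    """Full TOPAS pipeline: preprocess, pool, rank by RWR, prune.

    Returns the complete pruned subnetwork; use ``Module.largest_component``
    for the largest predicted module that evaluation metrics score.
    """
    config = config or TopasConfig()
    lcc, connectable = preprocess(net, seeds)
    pool = build_candidate_pool(lcc, connectable, config.d, config.on_shortest_paths_only)
    if pool.candidates:
        rwr = rwr_steady_state(lcc, connectable, config.rwr_params)
        pool = rank_candidates(pool, rwr)
    module = prune(connectable, pool, lcc)
    if module.graph.number_of_nodes() == 0:
        logger.warning("empty module: no connectable seed")
    return module
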