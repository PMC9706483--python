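"""Evaluation statistics for predicted disease modules.

Scoring metrics
---------------
* Seed Recovery Rate (SRR): fraction of connectable seeds recovered in the
  largest predicted module.
* Seed-to-Connector Ratio (SCR): seeds per connector in the largest
  predicted module; undefined when the module has no connector.

Set-overlap coefficients: Jaccard index |A∩B|/|A∪B| and the
Szymkiewicz–Simpson overlap coefficient |A∩B|/min(|A|,|B|).

Significance is assessed with a degree-aware subsampling null model: random
gene sets matched to the observed degree distribution (equal-occupancy
degree bins), used both for largest-connected-component size and for the
pathway-term overlap between seeds and connectors within module clusters.
Multiple testing across clusters is controlled with Benjamini–Hochberg FDR.

Empirical p-values use the (1 + count) / (1 + n) convention so p = 0 is
impossible. The test statistics are discrete, so these p-values are valid
but conservative; pass ``randomize_ties=True`` to draw the tie mass
uniformly, which makes null p-values exactly uniform (useful for
calibration checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import Module
from .graph import largest_connected_component

logger = logging.getLogger(__name__)

__all__ = [
    "EvalRecord",
    "NullDistribution",
    "ClusterRelevance",
    "seed_recovery_rate",
    "seed_connector_ratio",
    "connector_recall",
    "jaccard",
    "overlap_coefficient",
    "degree_aware_sample",
    "lcc_significance",
    "pathway_relevance",
    "bh_fdr",
    "evaluate_module",
    "records_to_tsv",
    "read_gmt",
    "gene_annotations",
    "read_partition",
]


@dataclass
class EvalRecord:
    """SRR/SCR summary for one (method, gene set, network) run."""

    method: str
    gene_set: str
    network: str
    srr: float
    scr: float | None
    n_seeds_in_module: int
    n_connectors_in_module: int
    n_connectable_seeds: int


@dataclass
class NullDistribution:
    """An observed statistic against its degree-aware permutation null."""

    n_samples: int
    observed: float
    samples: np.ndarray
    p_value: float
    seed: int | None = None


@dataclass
class ClusterRelevance:
    """Seed-connector pathway-term overlap for one module cluster."""

    cluster: str
    jaccard: float | None
    p_value: float | None
    p_adjusted: float | None
    significant: bool
    testable: bool


def seed_recovery_rate(module: Module, connectable_seeds: Iterable[str]) -> float:
    """|seeds of the largest module component ∩ connectable| / |connectable|."""
    connectable = set(connectable_seeds)
    if not connectable:
        raise ValueError("empty connectable seed set")
    top = module.largest_component()
    return len(top.seeds & connectable) / len(connectable)


def seed_connector_ratio(module: Module) -> float | None:
    """Seeds per connector in the largest module component; ``None`` when the
    module has no connector (only modules with >= 1 seed and >= 1 connector
    carry a defined ratio)."""
    top = module.largest_component()
    if not top.connectors:
        return None
    return len(top.seeds) / len(top.connectors)


def connector_recall(module: Module, true_connectors: Iterable[str]) -> float:
    """Fraction of known (e.g. planted) connectors recovered by the module."""
    truth = set(true_connectors)
    if not truth:
        raise ValueError("empty reference connector set")
    return len(module.connectors & truth) / len(truth)


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B|; defined as 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.info("jaccard of two empty sets: returning 0")
        return 0.0
    return len(sa & sb) / len(union)


def overlap_coefficient(a: Iterable, b: Iterable) -> float:
    """Szymkiewicz–Simpson coefficient |A∩B| / min(|A|,|B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient requires two non-empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


def _degree_bins(net: nx.Graph, bin_size: int) -> dict[str, int]:
    """Assign each node to an equal-occupancy degree bin (~bin_size nodes
    per bin after sorting by degree, ties broken by node ID)."""
    nodes = sorted(net.nodes, key=lambda n: (net.degree(n), n))
    n_bins = max(1, round(len(nodes) / bin_size))
    return {n: min(i * n_bins // len(nodes), n_bins - 1) for i, n in enumerate(nodes)}


def degree_aware_sample(
    net: nx.Graph,
    template: Iterable[str],
    rng: np.random.Generator,
    bin_size: int = 100,
    _bins: dict[str, int] | None = None,
    _members: list[list[str]] | None = None,
) -> set[str]:
    """Draw |template| distinct nodes degree-matched to the template.

    Each template node is replaced by a uniform draw from its degree bin;
    draws are without replacement within the sample. Template nodes may be
    re-drawn (self-inclusion allowed). If a bin is exhausted the nearest
    non-empty bin supplies the draw.
    """
    template = sorted(set(template))
    missing = [n for n in template if n not in net]
    if missing:
        raise KeyError(f"template nodes not in network: {missing[:5]}")
    bins = _bins if _bins is not None else _degree_bins(net, bin_size)
    if _members is None:
        n_bins = max(bins.values()) + 1
        members = [[] for _ in range(n_bins)]
        for n in sorted(bins):
            members[bins[n]].append(n)
    else:
        members = _members
    chosen: set[str] = set()
    for node in template:
        b = bins[node]
        for idx in sorted(range(len(members)), key=lambda i: (abs(i - b), i)):
            avail = [m for m in members[idx] if m not in chosen]
            if avail:
                if idx != b:
                    logger.debug("degree bin %d exhausted; falling back to bin %d", b, idx)
                chosen.add(avail[rng.integers(len(avail))])
                break
        else:  # pragma: no cover - template larger than network
            raise ValueError("cannot draw enough distinct nodes")
    return chosen


def _empirical_p(
    observed: float,
    samples: np.ndarray,
    rng: np.random.Generator | None = None,
    randomize_ties: bool = False,
) -> float:
    n = len(samples)
    greater = int(np.sum(samples > observed))
    ties = int(np.sum(samples == observed))
    if randomize_ties:
        if rng is None:
            raise ValueError("randomize_ties requires an rng")
        # Uniformly split the tie mass: exactly U(0,1] under the null.
        return (greater + float(rng.uniform()) * (ties + 1)) / (1 + n)
    return (1 + greater + ties) / (1 + n)


def lcc_significance(
    net: nx.Graph,
    genes: Iterable[str],
    n_samples: int = 10_000,
    seed: int | None = None,
    bin_size: int = 100,
    randomize_ties: bool = False,
) -> NullDistribution:
    """Degree-aware subsampling test for largest-connected-component size.

    The observed statistic is the LCC size of ``genes`` within the network;
    the null re-draws ``n_samples`` degree-matched gene sets and records
    their LCC sizes. Upper-tail empirical p with the +1 correction.
    """
    genes = set(genes) & set(net.nodes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes in the network")
    rng = np.random.default_rng(seed)
    bins = _degree_bins(net, bin_size)
    n_bins = max(bins.values()) + 1
    members: list[list[str]] = [[] for _ in range(n_bins)]
    for n in sorted(bins):
        members[bins[n]].append(n)
    adj = {n: set(net.neighbors(n)) for n in net.nodes}

    def lcc_size(nodes: set[str]) -> int:
        best, seen = 0, set()
        for start in nodes:
            if start in seen:
                continue
            comp, stack = 0, [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                comp += 1
                for v in adj[u]:
                    if v in nodes and v not in seen:
                        seen.add(v)
                        stack.append(v)
            best = max(best, comp)
        return best

    observed = lcc_size(genes)
    samples = np.empty(n_samples)
    for i in range(n_samples):
        draw = degree_aware_sample(net, genes, rng, bin_size, _bins=bins, _members=members)
        samples[i] = lcc_size(draw)
    p = _empirical_p(observed, samples, rng, randomize_ties)
    return NullDistribution(
        n_samples=n_samples, observed=float(observed), samples=samples, p_value=p, seed=seed
    )


def pathway_relevance(
    module: Module,
    partition: Mapping[str, str],
    annotations: Mapping[str, set[str]],
    net: nx.Graph,
    n_samples: int = 10_000,
    fdr: float = 0.05,
    seed: int | None = None,
    bin_size: int = 100,
) -> list[ClusterRelevance]:
    """Seed-connector pathway-term overlap per module cluster.

    For each cluster of the partition the observed statistic is the Jaccard
    index between the union of terms annotating its seed members and the
    union of terms annotating its connector members. The null resamples the
    connector members degree-aware and recomputes the overlap. Clusters
    whose seed or connector side has no annotated gene are untestable and
    are excluded from the Benjamini–Hochberg correction.
    """
    if not annotations:
        raise ValueError("empty annotation map")
    uncovered = module.nodes - set(partition)
    if uncovered:
        raise ValueError(f"partition does not cover the module: {sorted(uncovered)[:5]}")
    rng = np.random.default_rng(seed)
    bins = _degree_bins(net, bin_size)
    members_by_bin: list[list[str]] = [[] for _ in range(max(bins.values()) + 1)]
    for n in sorted(bins):
        members_by_bin[bins[n]].append(n)

    def terms_of(genes: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for g in genes:
            out |= annotations.get(g, set())
        return out

    clusters = sorted({partition[n] for n in module.nodes})
    results: list[ClusterRelevance] = []
    testable_idx: list[int] = []
    pvals: list[float] = []
    for cl in clusters:
        nodes = {n for n in module.nodes if partition[n] == cl}
        seed_members = nodes & module.seeds
        conn_members = nodes & module.connectors
        seed_terms = terms_of(seed_members)
        conn_terms = terms_of(conn_members)
        if not seed_terms or not conn_terms:
            results.append(ClusterRelevance(cl, None, None, None, False, False))
            continue
        observed = jaccard(seed_terms, conn_terms)
        samples = np.empty(n_samples)
        for i in range(n_samples):
            draw = degree_aware_sample(
                net, conn_members, rng, bin_size, _bins=bins, _members=members_by_bin
            )
            samples[i] = jaccard(seed_terms, terms_of(draw))
        p = _empirical_p(observed, samples)
        testable_idx.append(len(results))
        pvals.append(p)
        results.append(ClusterRelevance(cl, observed, p, None, False, True))
    if pvals:
        adjusted = bh_fdr(pvals)
        for idx, padj in zip(testable_idx, adjusted):
            rec = results[idx]
            results[idx] = ClusterRelevance(
                rec.cluster, rec.jaccard, rec.p_value, padj, padj < fdr, True
            )
    return results


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def evaluate_module(
    module: Module,
    connectable_seeds: Iterable[str],
    method: str = "",
    gene_set: str = "",
    network: str = "",
) -> EvalRecord:
    """SRR/SCR record for one prediction (scored on the largest component)."""
    top = module.largest_component()
    connectable = set(connectable_seeds)
    return EvalRecord(
        method=method,
        gene_set=gene_set,
        network=network,
        srr=seed_recovery_rate(module, connectable),
        scr=seed_connector_ratio(module),
        n_seeds_in_module=len(top.seeds),
        n_connectors_in_module=len(top.connectors),
        n_connectable_seeds=len(connectable),
    )


_RECORD_COLUMNS = [
    "method",
    "gene_set",
    "network",
    "srr",
    "scr",
    "n_seeds_in_module",
    "n_connectors_in_module",
    "n_connectable_seeds",
]


def records_to_tsv(records: Sequence[EvalRecord], path: str | Path) -> None:
    """Write evaluation records as a TSV with a stable column order; an
    undefined SCR is rendered as NA."""
    df = pd.DataFrame([vars(r) for r in records], columns=_RECORD_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene-set annotations in GMT format: term, description, genes."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields")
        terms[fields[0]] = {g for g in fields[2:] if g}
    return terms


def gene_annotations(terms: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Invert a term→genes map into gene→terms."""
    out: dict[str, set[str]] = {}
    for term, genes in terms.items():
        for g in genes:
            out.setdefault(g, set()).add(term)
    return out


def read_partition(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (node, cluster-id) partition table."""
    partition: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: partition rows need 2 columns")
        partition[fields[0].strip()] = fields[1].strip()
    return partition
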