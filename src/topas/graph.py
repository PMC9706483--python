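"""Graph data model, file I/O, identifier mapping and elementary graph operations.

Networks are plain :class:`networkx.Graph` objects over opaque, case-sensitive
string node identifiers. Graphs are undirected and simple: self-loops are
dropped on read and parallel input rows collapse to a single edge. Confidence
scores, when present, are kept as the ``weight`` edge attribute but are
metadata only — every algorithmic step downstream operates on the unweighted
topology.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "read_edge_list",
    "write_edge_list",
    "read_seed_file",
    "load_mapping",
    "map_identifiers",
    "make_seed_set",
    "connected_components",
    "largest_connected_component",
    "bfs_distances",
    "induced_subgraph",
]


@dataclass
class SeedSet:
    """A seed gene set, split by mapping and connectability status.

    ``mapped`` are the raw identifiers (after optional ID translation) found
    in the network; ``unmapped`` is the remainder. ``connectable`` is filled
    in by preprocessing: the mapped seeds lying in the network component used
    for module building.
    """

    raw_ids: list[str]
    mapped: set[str] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)
    connectable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if set(self.mapped) | set(self.unmapped) != set(self.raw_ids):
            raise ValueError("mapped and unmapped must partition raw_ids")
        if not self.connectable <= set(self.mapped):
            raise ValueError("connectable seeds must be a subset of mapped seeds")


def _detect_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(
    path: str | Path,
    score_column: str | int | None = None,
    threshold: float | None = None,
    delimiter: str | None = None,
) -> nx.Graph:
    """Read an undirected network from a TSV/CSV edge list.

    The first two columns are node identifiers; ``score_column`` (a header
    name or 0-based column index) selects an optional numeric confidence
    column. When ``threshold`` is given only edges with score >= threshold
    are kept (the convention used for confidence-cutoff interactomes such as
    FunCoup >= 0.8 or STRING >= 800). Self-loops are dropped; duplicate rows
    collapse to one edge keeping the maximum score.

    A header row is auto-detected when the first row has a third field that
    does not parse as a number.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"edge list not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return nx.Graph()
        delim = delimiter or _detect_delimiter(first)
        fh.seek(0)
        if delim == " ":
            rows = [(i, line.split()) for i, line in enumerate(fh, start=1) if line.strip()]
        else:
            rows = [
                (i, row)
                for i, row in enumerate(csv.reader(fh, delimiter=delim), start=1)
                if any(tok.strip() for tok in row)
            ]

    header: list[str] | None = None
    if rows and len(rows[0][1]) >= 3 and not _is_number(rows[0][1][2]):
        header = [tok.strip() for tok in rows[0][1]]
        rows = rows[1:]

    score_idx: int | None = None
    if score_column is not None:
        if isinstance(score_column, int):
            score_idx = score_column
        else:
            if header is None or score_column not in header:
                raise ValueError(f"score column {score_column!r} not found in header {header}")
            score_idx = header.index(score_column)
    if threshold is not None and score_idx is None:
        raise ValueError("a threshold requires a score_column")

    net = nx.Graph()
    n_loops = 0
    for lineno, row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: malformed row (need >= 2 columns): {row!r}")
        u, v = row[0].strip(), row[1].strip()
        if not u or not v:
            raise ValueError(f"{path}:{lineno}: empty node identifier")
        score = None
        if score_idx is not None:
            if score_idx >= len(row):
                raise ValueError(f"{path}:{lineno}: missing score column {score_idx}")
            try:
                score = float(row[score_idx])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {row[score_idx]!r}") from exc
        if u == v:
            n_loops += 1
            continue
        if threshold is not None and score < threshold:
            continue
        if net.has_edge(u, v):
            if score is not None:
                prev = net.edges[u, v].get("weight")
                if prev is None or score > prev:
                    net.edges[u, v]["weight"] = score
        elif score is not None:
            net.add_edge(u, v, weight=score)
        else:
            net.add_edge(u, v)
    if n_loops:
        logger.info("dropped %d self-loop rows from %s", n_loops, path)
    return net


def write_edge_list(net: nx.Graph, path: str | Path, delimiter: str = "\t") -> None:
    """Write a network back to an edge-list TSV (deterministic row order)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            w = net.edges[u, v].get("weight")
            if w is None:
                fh.write(f"{u}{delimiter}{v}\n")
            else:
                fh.write(f"{u}{delimiter}{v}{delimiter}{w:g}\n")


def read_seed_file(path: str | Path) -> list[str]:
    """Read a plain-text seed list, one identifier per line; '#' comments and
    blank lines are ignored; input order is preserved, duplicates dropped."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"seed file not found: {path}")
    out: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


def load_mapping(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Load a two-column (source, target) identifier mapping table."""
    mapping: dict[str, str] = {}
    with open(Path(path), newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or not any(tok.strip() for tok in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: mapping rows need 2 columns")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def map_identifiers(
    ids: Sequence[str], mapping: Mapping[str, str]
) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Translate identifiers through a many-to-one mapping table.

    Returns ``(mapped, unmapped, collisions)``. Input order is preserved; an
    identifier without a mapping goes to ``unmapped``. When several sources
    map to the same target the target is kept once and the collision is
    reported as ``{target: [sources...]}`` so the resolution is visible
    rather than silent.
    """
    if not ids:
        raise ValueError("empty identifier list")
    if not mapping:
        raise ValueError("empty mapping table")
    mapped: list[str] = []
    unmapped: list[str] = []
    sources: dict[str, list[str]] = {}
    for raw in ids:
        tgt = mapping.get(raw)
        if tgt is None:
            unmapped.append(raw)
            continue
        sources.setdefault(tgt, []).append(raw)
        if len(sources[tgt]) == 1:
            mapped.append(tgt)
    collisions = {t: s for t, s in sources.items() if len(s) > 1}
    if collisions:
        logger.warning("identifier collisions: %s", collisions)
    return mapped, unmapped, collisions


def make_seed_set(
    raw_ids: Sequence[str],
    net: nx.Graph,
    mapping: Mapping[str, str] | None = None,
) -> SeedSet:
    """Build a :class:`SeedSet` for a network, optionally translating IDs first."""
    ids = list(raw_ids)
    if mapping is not None:
        translated, untranslated, _ = map_identifiers(ids, mapping)
        in_net = [g for g in translated if g in net]
        off_net = [g for g in translated if g not in net]
        return SeedSet(
            raw_ids=translated + untranslated,
            mapped=set(in_net),
            unmapped=set(off_net) | set(untranslated),
        )
    return SeedSet(
        raw_ids=ids,
        mapped={g for g in ids if g in net},
        unmapped={g for g in ids if g not in net},
    )


def connected_components(net: nx.Graph) -> list[set[str]]:
    """Connected components, ordered by size descending then smallest member ID."""
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def largest_connected_component(
    net: nx.Graph, genes: Iterable[str] | None = None
) -> nx.Graph | set[str]:
    """Largest connected component of the network, or of a gene set within it.

    With ``genes`` omitted, returns the subgraph induced by the largest
    component (ties broken by smallest member ID). With ``genes`` given,
    returns the largest connected *node set* among the subgraph induced by
    those genes.
    """
    if genes is not None:
        present = set(genes) & set(net.nodes)
        if not present:
            return set()
        sub = net.subgraph(present)
        comps = connected_components(sub)
        return comps[0]
    if net.number_of_nodes() == 0:
        return nx.Graph()
    comps = connected_components(net)
    return net.subgraph(comps[0]).copy()


def bfs_distances(net: nx.Graph, source: str, max_depth: int) -> dict[str, int]:
    """Unweighted hop distances from ``source``, truncated at ``max_depth``."""
    if source not in net:
        raise KeyError(f"source node {source!r} not in network")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    return dict(nx.single_source_shortest_path_length(net, source, cutoff=max_depth))


def induced_subgraph(net: nx.Graph, nodes: Iterable[str]) -> nx.Graph:
    """Subgraph induced by ``nodes``; identifiers absent from the network are
    silently dropped (with a log line). Edge weights are preserved."""
    wanted = set(nodes)
    extra = wanted - set(net.nodes)
    if extra:
        logger.info("induced_subgraph: dropping %d unknown node(s)", len(extra))
    return net.subgraph(wanted - extra).copy()
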