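"""Protein–protein interaction handling.

Loads STRING-dialect edge lists thresholded on the combined confidence
score, extracts per-protein interactor sets, intersects them for the shared
("Venn") interactors, and ranks mediator candidates — non-anchor proteins
adjacent to many anchors — as hub proposals for the pathway linking two
seed proteins.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx

from ._io import read_lines

logger = logging.getLogger(__name__)


class PPINetwork:
    """Undirected confidence-weighted protein network.

    No self-loops; scores in [0, 1]; a duplicate pair keeps the maximum
    score.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        self._graph = nx.Graph()
        for a, b, score in edges:
            self.add_edge(a, b, score)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        existing = self._graph.get_edge_data(a, b)
        if existing is None or existing["score"] < score:
            self._graph.add_edge(a, b, score=score)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, score) with a < b, sorted (stable for writers)."""
        out = []
        for a, b, data in self._graph.edges(data=True):
            x, y = (a, b) if a < b else (b, a)
            out.append((x, y, data["score"]))
        return sorted(out)

    def score(self, a: str, b: str) -> float | None:
        data = self._graph.get_edge_data(a, b)
        return None if data is None else data["score"]

    def __contains__(self, protein: str) -> bool:
        return protein in self._graph

    def interactors(self, protein: str) -> frozenset[str]:
        """Adjacency set of a protein (itself excluded).

        An absent node yields the empty set with a logged notice.
        """
        if protein not in self._graph:
            logger.info("protein %r not in network; empty interactor set",
                        protein)
            return frozenset()
        return frozenset(self._graph.neighbors(protein)) - {protein}


def interactors(net: PPINetwork, protein: str) -> frozenset[str]:
    """Functional alias for :meth:`PPINetwork.interactors`."""
    return net.interactors(protein)


def common_interactors(net: PPINetwork, p1: str, p2: str) -> frozenset[str]:
    """Interactors shared by two seed proteins (the seeds excluded)."""
    return (net.interactors(p1) & net.interactors(p2)) - {p1, p2}


def venn_summary(net: PPINetwork, p1: str, p2: str) -> dict:
    """Two-set Venn counts for a seed pair's interactor sets."""
    a = net.interactors(p1)
    b = net.interactors(p2)
    common = (a & b) - {p1, p2}
    return {
        "seed_a": p1, "seed_b": p2,
        "n_a": len(a), "n_b": len(b),
        "n_common": len(common), "n_union": len(a | b),
        "common": sorted(common),
    }


def parse_string_links(source: str | os.PathLike | IO[str],
                       cutoff: float) -> PPINetwork:
    """Load a STRING-dialect TSV keeping edges with score > cutoff (strict).

    Rows are ``protein1 protein2 combined_score``; the score scale is
    auto-detected (any value > 1 means STRING's 0–999 integer scale, which
    is divided by 1000).  Malformed rows are skipped with a logged warning;
    a score outside both scales is a hard error.  An optional header row is
    tolerated.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    rows: list[tuple[str, str, float, int]] = []
    for number, raw in enumerate(read_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace("\t", " ").split()
        if len(fields) < 3:
            logger.warning("skipping malformed edge line %d: %r", number, raw)
            continue
        a, b = fields[0], fields[1]
        try:
            score = float(fields[2])
        except ValueError:
            if not rows and number == 1:
                continue  # header row
            logger.warning("skipping malformed edge line %d: %r", number, raw)
            continue
        if score < 0.0 or score > 1000.0:
            raise ValueError(
                f"line {number}: score {score} outside both the [0, 1] and "
                f"the STRING 0–999 scales")
        if a == b:
            logger.warning("skipping self-loop on line %d: %r", number, raw)
            continue
        rows.append((a, b, score, number))
    scale = 1000.0 if any(score > 1.0 for _, _, score, _ in rows) else 1.0
    best: dict[tuple[str, str], float] = {}
    for a, b, score, _ in rows:
        key = (a, b) if a < b else (b, a)
        value = score / scale
        if best.get(key, -1.0) < value:
            best[key] = value
    net = PPINetwork()
    for (a, b), score in best.items():
        if score > cutoff:
            net.add_edge(a, b, score)
    return net


@dataclass
class MediatorRanking:
    """Candidate hubs ranked by the number of distinct anchors they touch.

    Rows are ``(candidate, n_links_to_anchors, linked_anchors)``, sorted by
    link count descending then candidate id ascending; anchors themselves
    are never candidates.
    """

    anchors: frozenset[str]
    rows: list[tuple[str, int, tuple[str, ...]]]

    def top(self, n: int = 5) -> list[str]:
        return [row[0] for row in self.rows[:n]]

    def to_tsv(self, target: str | os.PathLike | IO[str] | None = None
               ) -> str | None:
        lines = ["candidate\tn_links\tlinked_anchors"]
        lines += [f"{c}\t{n}\t{','.join(linked)}" for c, n, linked in self.rows]
        text = "\n".join(lines) + "\n"
        if target is None:
            return text
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w", encoding="utf-8") as handle:
                handle.write(text)
        return None


def rank_mediators(net: PPINetwork, anchors: Iterable[str],
                   min_links: int = 2) -> MediatorRanking:
    """Rank non-anchor proteins by distinct-anchor adjacency (global search).

    A candidate qualifies with at least ``min_links`` anchor neighbours.
    """
    anchor_set = frozenset(anchors)
    if not anchor_set:
        raise ValueError("anchors must be nonempty")
    linked: dict[str, set[str]] = {}
    for anchor in anchor_set:
        for neighbour in net.interactors(anchor):
            if neighbour not in anchor_set:
                linked.setdefault(neighbour, set()).add(anchor)
    rows = [(candidate, len(hits), tuple(sorted(hits)))
            for candidate, hits in linked.items() if len(hits) >= min_links]
    rows.sort(key=lambda row: (-row[1], row[0]))
    return MediatorRanking(anchors=anchor_set, rows=rows)
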