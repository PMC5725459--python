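"""Scored protein-interaction networks.

A :class:`ScoredNetwork` is an undirected graph whose edges carry a
confidence score in [0, 1], in the style of a STRING combined-score
edge list.  Readers deduplicate reversed pairs (keeping the maximum
score) and reject out-of-range scores with the offending line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


class ScoredNetwork:
    """Undirected graph with edge scores in [0, 1].

    Self-loops are rejected; adding a duplicate pair keeps the maximum
    score (and counts the collision in ``n_deduplicated``).
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.n_deduplicated = 0

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} for {a}-{b} outside [0, 1]")
        if self.graph.has_edge(a, b):
            self.n_deduplicated += 1
            old = self.graph[a][b]["score"]
            if score != old:
                logger.info("duplicate edge %s-%s: keeping max(%g, %g)", a, b, old, score)
            score = max(score, old)
        self.graph.add_edge(a, b, score=score)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "ScoredNetwork":
        net = cls()
        for a, b, s in edges:
            net.add_edge(a, b, s)
        return net

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def score(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return self.graph[a][b]["score"]
        return None

    def has_interaction(self, a: str, b: str, min_score: float = 0.0) -> bool:
        s = self.score(a, b)
        return s is not None and s >= min_score

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, data in self.graph.edges(data=True):
            x, y = _key(a, b)
            yield x, y, data["score"]

    def sorted_edges(self) -> list[tuple[str, str, float]]:
        return sorted(self.edges())

    def adjacency_matrix(self, nodelist: list[str], weighted: bool = True) -> np.ndarray:
        mat = nx.to_numpy_array(self.graph, nodelist=nodelist, weight="score")
        if not weighted:
            mat = (mat > 0).astype(float)
        return mat

    def thresholded(self, min_score: float) -> "ScoredNetwork":
        """Copy containing only edges with score >= min_score (inclusive)."""
        net = ScoredNetwork()
        for n in self.graph.nodes:
            net.add_node(n)
        for a, b, s in self.edges():
            if s >= min_score:
                net.add_edge(a, b, s)
        return net

    # -- I/O ----------------------------------------------------------

    def write_edge_list(self, path: str | Path) -> None:
        lines = ["protein1\tprotein2\tscore"]
        for a, b, s in self.sorted_edges():
            lines.append(f"{a}\t{b}\t{s:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_sif(self, path: str | Path, relation: str = "pp") -> None:
        """Cytoscape SIF export of the edge set."""
        lines = [f"{a}\t{relation}\t{b}" for a, b, _ in self.sorted_edges()]
        Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> ScoredNetwork:
    """Read a TSV/whitespace edge list ``protein1 protein2 score``.

    A header line is tolerated.  Reversed duplicates are merged keeping
    the maximum score; a score outside [0, 1] raises with the line
    number.
    """
    net = ScoredNetwork()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            if lineno == 1 and raw.lower() == "score":
                continue  # header
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: score {raw!r} is not a number") from exc
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            net.add_edge(a, b, score)
    return net
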