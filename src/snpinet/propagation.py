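"""Random walk with restart over a scored interaction network.

Seed proteins (products of the subpopulation-specific genes) are
extended to the proteins most visited by a walker that at every step
either moves to a neighbour (with probability proportional to edge
score) or restarts uniformly at a seed.  The stationary distribution
solves r = c e + (1 - c) W r with restart probability c, uniform seed
vector e and column-normalized weighted adjacency W; columns of
isolated nodes redirect to e so W stays stochastic and the score mass
always sums to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .networks import ScoredNetwork

PairKey = tuple[str, str]


def _pair(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class PropagationResult:
    scores: dict[str, float]
    seeds: frozenset[str]
    restart_probability: float
    iterations: int

    def score_of(self, node: str) -> float:
        return self.scores.get(node, 0.0)

    def seed_mass(self) -> float:
        return sum(self.scores[s] for s in self.seeds)

    def to_dataframe(self):
        import pandas as pd

        ranked = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "protein": [n for n, _ in ranked],
                "score": [s for _, s in ranked],
                "rank": range(1, len(ranked) + 1),
                "is_seed": [n in self.seeds for n, _ in ranked],
            }
        )


def _transition_matrix(
    network: ScoredNetwork, nodelist: list[str], seed_vec: np.ndarray, weighted: bool
) -> np.ndarray:
    A = network.adjacency_matrix(nodelist, weighted=weighted)
    colsums = A.sum(axis=0)
    W = np.zeros_like(A)
    nz = colsums > 0
    W[:, nz] = A[:, nz] / colsums[nz]
    # dangling columns: walker restarts at the seeds
    W[:, ~nz] = seed_vec[:, None]
    return W


def rwr(
    network: ScoredNetwork,
    seeds: Iterable[str],
    restart_probability: float = 0.95,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    weighted: bool = True,
) -> PropagationResult:
    """Fixed point of the restart walk, by power iteration.

    Stops when the L1 change between iterates falls below ``tol``.
    Raises if a seed is missing from the network; unreachable nodes end
    with score exactly zero (no probability can flow to them).
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = [s for s in sorted(seeds) if not network.has_node(s)]
    if missing:
        raise KeyError(f"seed node(s) not in network: {missing}")
    c = restart_probability
    if not 0.0 < c <= 1.0:
        raise ValueError("restart_probability must be in (0, 1]")
    nodelist = network.nodes
    index = {n: i for i, n in enumerate(nodelist)}
    e = np.zeros(len(nodelist))
    e[[index[s] for s in seeds]] = 1.0 / len(seeds)
    if c == 1.0:
        return PropagationResult(
            scores=dict(zip(nodelist, e)), seeds=seeds,
            restart_probability=c, iterations=0,
        )
    W = _transition_matrix(network, nodelist, e, weighted)
    r = e.copy()
    for iteration in range(1, max_iter + 1):
        r_new = c * e + (1.0 - c) * (W @ r)
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    else:
        raise RuntimeError(f"RWR did not converge in {max_iter} iterations")
    return PropagationResult(
        scores=dict(zip(nodelist, r)), seeds=seeds,
        restart_probability=c, iterations=iteration,
    )


def rwr_linear_solve(
    network: ScoredNetwork,
    seeds: Iterable[str],
    restart_probability: float = 0.95,
    weighted: bool = True,
) -> dict[str, float]:
    """Direct dense solution r = c (I - (1-c) W)^-1 e; oracle-grade
    reference for small networks."""
    seeds = frozenset(seeds)
    c = restart_probability
    nodelist = network.nodes
    index = {n: i for i, n in enumerate(nodelist)}
    e = np.zeros(len(nodelist))
    e[[index[s] for s in seeds]] = 1.0 / len(seeds)
    W = _transition_matrix(network, nodelist, e, weighted)
    r = c * np.linalg.solve(np.eye(len(nodelist)) - (1.0 - c) * W, e)
    return dict(zip(nodelist, r))


def top_fraction(result: PropagationResult, fraction: float = 0.05) -> set[str]:
    """Extended protein set: the top ``fraction`` of nodes with nonzero
    score, ranked by (score desc, protein id asc); the count is the
    ceiling of fraction x (number of nonzero-score nodes).  Seeds rank
    like any other node.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    nonzero = [(n, s) for n, s in result.scores.items() if s > 0.0]
    if not nonzero:
        return set()
    nonzero.sort(key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(nonzero))
    return {n for n, _ in nonzero[:k]}


def extract_subnetwork(
    proteins: set[str], network: ScoredNetwork, min_score: float = 0.7
) -> set[tuple[str, str, float]]:
    """Edges with both endpoints in ``proteins`` and score >= min_score
    (inclusive)."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    return {
        (a, b, s)
        for a, b, s in network.edges()
        if a in proteins and b in proteins and s >= min_score
    }


def lineage_specific_edges(
    edge_set: Iterable[tuple[str, str, float]] | Iterable[PairKey],
    profiles: Mapping[PairKey, Mapping[str, str]],
    excluded_species: Sequence[str] = ("cat", "horse", "pig", "cow"),
) -> tuple[set[PairKey], dict[str, int]]:
    """Edges absent (or unknown) in every excluded related species.

    ``profiles`` maps a protein pair to per-species interaction states
    in {'present', 'absent', 'unknown'}; a pair without a profile is
    unknown everywhere.  Returns the kept pairs and counts split into
    'known_absent' (all excluded species known-absent) and
    'unknown_containing'.
    """
    kept: set[PairKey] = set()
    counts = {"known_absent": 0, "unknown_containing": 0}
    for edge in edge_set:
        a, b = edge[0], edge[1]
        pair = _pair(a, b)
        states = profiles.get(pair, {})
        sp_states = [states.get(sp, "unknown") for sp in excluded_species]
        if any(st == "present" for st in sp_states):
            continue
        kept.add(pair)
        if all(st == "absent" for st in sp_states):
            counts["known_absent"] += 1
        else:
            counts["unknown_containing"] += 1
    return kept, counts


@dataclass
class EnrichmentTable:
    """2x2 within/between interaction table with a one-sided p."""

    within_interacting: int
    within_possible: int
    between_interacting: int
    between_possible: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "within": {
                "interacting": self.within_interacting,
                "non_interacting": self.within_possible - self.within_interacting,
            },
            "between": {
                "interacting": self.between_interacting,
                "non_interacting": self.between_possible - self.between_interacting,
            },
            "p_value": self.p_value,
        }


def within_between_enrichment(
    set_a: set[str],
    set_b: set[str],
    edge_set: Iterable[tuple[str, str, float]] | Iterable[PairKey],
) -> EnrichmentTable:
    """Test whether interactions concentrate within the two protein
    sets rather than between them.

    Possible pairs split into within (A-A or B-B) and between (A-B);
    the one-sided p is the hypergeometric upper tail for the number of
    within-pairs among the interacting pairs.  Edges touching proteins
    outside A u B are ignored.
    """
    if not set_a or not set_b:
        raise ValueError("both protein sets must be non-empty")
    if set_a & set_b:
        raise ValueError("protein sets must be disjoint")
    n_a, n_b = len(set_a), len(set_b)
    within_possible = n_a * (n_a - 1) // 2 + n_b * (n_b - 1) // 2
    between_possible = n_a * n_b
    within = between = 0
    seen: set[PairKey] = set()
    for edge in edge_set:
        a, b = edge[0], edge[1]
        pair = _pair(a, b)
        if pair in seen:
            continue
        seen.add(pair)
        if (a in set_a and b in set_a) or (a in set_b and b in set_b):
            within += 1
        elif (a in set_a and b in set_b) or (a in set_b and b in set_a):
            between += 1
    total_interacting = within + between
    if total_interacting == 0:
        p = 1.0
    else:
        p = float(
            hypergeom.sf(
                within - 1,
                within_possible + between_possible,
                within_possible,
                total_interacting,
            )
        )
    return EnrichmentTable(
        within_interacting=within,
        within_possible=within_possible,
        between_interacting=between,
        between_possible=between_possible,
        p_value=p,
    )


def write_ranked_scores(result: PropagationResult, path: str | Path) -> None:
    result.to_dataframe().to_csv(path, sep="\t", index=False)
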