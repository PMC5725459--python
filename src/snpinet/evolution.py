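"""Cross-species interaction transfer and ancestral reconstruction.

Dog protein pairs are transferred to related species through ortholog
groups: a pair counts as interacting in a species when strictly more
than half of all possible cross pairs between the two groups' members
interact there (credible edges only, score >= 0.7).  The resulting
per-species presence/absence/unknown profiles are placed on a rooted
species tree and ancestral states are reconstructed by Fitch maximum
parsimony; gains (0 -> 1) and losses (1 -> 0) are accounted per branch
with denominators (pairs at risk) and a randomization test against
resamples of the profiled pair universe.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .networks import ScoredNetwork
from .trees import SpeciesTree, TreeNode

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"

# Fitch state sets as bitmasks: absent=1, present=2, either=3.
_SET_OF = {ABSENT: 1, PRESENT: 2, UNKNOWN: 3}
_STATE_OF_BIT = {1: 0, 2: 1}


def _pair(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


# -- ortholog map ------------------------------------------------------


class OrthologMap:
    """(species, protein) -> ortholog group, with the inverse index."""

    def __init__(self) -> None:
        self._group_of: dict[tuple[str, str], str] = {}
        self._members: dict[tuple[str, str], list[str]] = {}

    def add(self, species: str, protein: str, group: str) -> None:
        key = (species, protein)
        if key in self._group_of and self._group_of[key] != group:
            raise ValueError(
                f"{protein} ({species}) already mapped to {self._group_of[key]}"
            )
        if key in self._group_of:
            return
        self._group_of[key] = group
        self._members.setdefault((group, species), []).append(protein)

    def group_of(self, species: str, protein: str) -> str | None:
        return self._group_of.get((species, protein))

    def members(self, group: str, species: str) -> list[str]:
        return list(self._members.get((group, species), []))

    def write_tsv(self, path: str | Path) -> None:
        lines = ["species\tprotein_id\tgroup_id"]
        for (species, protein), group in sorted(self._group_of.items()):
            lines.append(f"{species}\t{protein}\t{group}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        omap = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["species", "protein_id", "group_id"]:
                raise ValueError(f"{path}: unexpected header {header}")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                species, protein, group = line.split("\t")
                omap.add(species, protein, group)
        return omap


# -- interaction transfer ----------------------------------------------


def transfer_interaction(
    pair: PairKey,
    species: str,
    ortholog_map: OrthologMap,
    species_network: ScoredNetwork,
    min_score: float = 0.7,
    focal_species: str = "dog",
) -> str:
    """State of a focal protein pair's interaction in another species.

    With ortholog groups of m and k members in the species, the
    interaction is 'present' iff strictly more than half of the m x k
    cross pairs interact with a credible score; 'unknown' when either
    group is empty in the species or a focal protein is unmapped.
    A protein paired with itself (overlapping groups) is excluded from
    the possible-pair count.
    """
    p, q = pair
    group_p = ortholog_map.group_of(focal_species, p)
    group_q = ortholog_map.group_of(focal_species, q)
    if group_p is None or group_q is None:
        logger.info("pair %s-%s: focal protein missing from ortholog map", p, q)
        return UNKNOWN
    members_p = ortholog_map.members(group_p, species)
    members_q = ortholog_map.members(group_q, species)
    if not members_p or not members_q:
        return UNKNOWN
    possible: set[PairKey] = set()
    for a in members_p:
        for b in members_q:
            if a == b:
                continue
            possible.add(_pair(a, b))
    if not possible:
        return UNKNOWN
    interacting = sum(
        1 for a, b in possible if species_network.has_interaction(a, b, min_score)
    )
    return PRESENT if interacting / len(possible) > 0.5 else ABSENT


@dataclass
class InteractionProfile:
    """Per-species interaction states for one focal protein pair."""

    pair: PairKey
    states: dict[str, str]
    focal_species: str = "dog"

    def __post_init__(self) -> None:
        if self.states.get(self.focal_species, UNKNOWN) == UNKNOWN:
            raise ValueError(
                f"pair {self.pair}: focal species state must be known"
            )
        for sp, st in self.states.items():
            if st not in (PRESENT, ABSENT, UNKNOWN):
                raise ValueError(f"invalid state {st!r} for {sp}")

    def state(self, species: str) -> str:
        return self.states.get(species, UNKNOWN)


def build_profiles(
    pairs: Iterable[PairKey],
    species: Sequence[str],
    ortholog_map: OrthologMap,
    species_networks: Mapping[str, ScoredNetwork],
    focal_network: ScoredNetwork,
    min_score: float = 0.7,
    focal_species: str = "dog",
) -> dict[PairKey, InteractionProfile]:
    """Transfer every pair to every species; the focal state is read
    directly from the focal network (present iff a credible edge)."""
    profiles: dict[PairKey, InteractionProfile] = {}
    for raw in pairs:
        pair = _pair(*raw)
        states = {
            focal_species: PRESENT
            if focal_network.has_interaction(*pair, min_score)
            else ABSENT
        }
        for sp in species:
            states[sp] = transfer_interaction(
                pair, sp, ortholog_map, species_networks[sp],
                min_score=min_score, focal_species=focal_species,
            )
        profiles[pair] = InteractionProfile(
            pair=pair, states=states, focal_species=focal_species
        )
    return profiles


# -- Fitch maximum parsimony ------------------------------------------


@dataclass
class FitchResult:
    """Reconstruction of one binary interaction character."""

    node_states: dict[str, int]  # resolved 0/1 per node (tips included)
    state_sets: dict[str, int]  # preliminary Fitch sets (bitmasks)
    score: int  # minimum number of state changes


def fitch_reconstruct(
    tree: SpeciesTree,
    tip_states: Mapping[str, str],
    outgroup: str = "mouse",
) -> FitchResult:
    """Fitch small parsimony for a binary presence/absence character.

    Unknown tips contribute the unconstrained set {0,1}.  The bottom-up
    pass counts union events (the parsimony score); the top-down pass
    resolves ambiguity by preferring the parent's resolved state, which
    pushes changes away from the root.  Root ambiguity is resolved by
    the outgroup state — taken from the tree if the outgroup is a tip,
    otherwise from ``tip_states`` — and falls back to absent (0) when
    the outgroup state is unknown.
    """
    tips = tree.tip_names()
    known = [
        t for t in tips if tip_states.get(t, UNKNOWN) != UNKNOWN
    ]
    if not known:
        raise ValueError("all tip states unknown; nothing to reconstruct")

    state_sets: dict[str, int] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            state_sets[node.name] = _SET_OF[tip_states.get(node.name, UNKNOWN)]
        else:
            inter = 3
            union = 0
            for child in node.children:
                inter &= state_sets[child.name]
                union |= state_sets[child.name]
            if inter:
                state_sets[node.name] = inter
            else:
                state_sets[node.name] = union
                score += 1

    node_states: dict[str, int] = {}
    for node in tree.preorder():
        sset = state_sets[node.name]
        if sset in (1, 2):
            node_states[node.name] = _STATE_OF_BIT[sset]
        elif node.parent is not None:
            node_states[node.name] = node_states[node.parent.name]
        else:
            node_states[node.name] = _root_resolution(tree, tip_states, outgroup)
    return FitchResult(node_states=node_states, state_sets=state_sets, score=score)


def _root_resolution(
    tree: SpeciesTree, tip_states: Mapping[str, str], outgroup: str
) -> int:
    og_state = tip_states.get(outgroup, UNKNOWN)
    if og_state == PRESENT:
        return 1
    return 0


def fitch_score_bruteforce(
    tree: SpeciesTree, tip_states: Mapping[str, str]
) -> int:
    """Minimum change count by exhaustive enumeration of all ancestral
    (and unknown-tip) labelings; exponential-time oracle for tests."""
    free = [n.name for n in tree.preorder()
            if not n.is_leaf or tip_states.get(n.name, UNKNOWN) == UNKNOWN]
    fixed = {
        n.name: 1 if tip_states[n.name] == PRESENT else 0
        for n in tree.tips()
        if tip_states.get(n.name, UNKNOWN) != UNKNOWN
    }
    if not fixed:
        raise ValueError("all tip states unknown")
    edges = [
        (n.parent.name, n.name) for n in tree.preorder() if n.parent is not None
    ]
    best = math.inf
    for bits in range(2 ** len(free)):
        labels = dict(fixed)
        for i, name in enumerate(free):
            labels[name] = (bits >> i) & 1
        changes = sum(1 for u, v in edges if labels[u] != labels[v])
        best = min(best, changes)
    return int(best)


# -- branch accounting -------------------------------------------------


@dataclass
class BranchChange:
    """Gain/loss accounting for one branch over a set of pairs."""

    branch: str  # child-node name
    parent: str
    gains: int = 0
    losses: int = 0
    n_parent_absent: int = 0  # pairs without interaction at the parent
    n_parent_present: int = 0

    @property
    def gain_fraction(self) -> float | None:
        if self.n_parent_absent == 0:
            return None
        return self.gains / self.n_parent_absent

    @property
    def loss_fraction(self) -> float | None:
        if self.n_parent_present == 0:
            return None
        return self.losses / self.n_parent_present


@dataclass
class BranchChangeSummary:
    branches: dict[str, BranchChange]
    n_pairs: int
    randomization_p: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for name, bc in self.branches.items():
            rows.append(
                {
                    "branch": name,
                    "parent": bc.parent,
                    "gains": bc.gains,
                    "losses": bc.losses,
                    "n_parent_absent": bc.n_parent_absent,
                    "n_parent_present": bc.n_parent_present,
                    "gain_fraction": bc.gain_fraction,
                    "loss_fraction": bc.loss_fraction,
                    "randomization_p": self.randomization_p.get(name),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def branch_change_summary(
    tree: SpeciesTree,
    reconstructions: Mapping[PairKey, FitchResult],
) -> BranchChangeSummary:
    """Per-branch gains, losses, at-risk denominators and fractions.

    For branch parent -> child: gains = pairs absent at the parent and
    present at the child; gain_fraction = gains / pairs absent at the
    parent (None when the denominator is zero), and symmetrically for
    losses.
    """
    branches: dict[str, BranchChange] = {}
    nodes = [n for n in tree.preorder() if n.parent is not None]
    for node in nodes:
        branches[node.name] = BranchChange(branch=node.name, parent=node.parent.name)
    for fr in reconstructions.values():
        for node in nodes:
            bc = branches[node.name]
            parent_state = fr.node_states[node.parent.name]
            child_state = fr.node_states[node.name]
            if parent_state == 0:
                bc.n_parent_absent += 1
                if child_state == 1:
                    bc.gains += 1
            else:
                bc.n_parent_present += 1
                if child_state == 0:
                    bc.losses += 1
    return BranchChangeSummary(branches=branches, n_pairs=len(reconstructions))


# -- randomization test ------------------------------------------------


def _gain_arrays(
    tree: SpeciesTree, reconstructions: Sequence[FitchResult]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    branch_names = tree.branches()
    parent_of = {
        n.name: n.parent.name for n in tree.preorder() if n.parent is not None
    }
    n = len(reconstructions)
    gain = np.zeros((n, len(branch_names)), dtype=bool)
    at_risk = np.zeros((n, len(branch_names)), dtype=bool)
    for i, fr in enumerate(reconstructions):
        for j, b in enumerate(branch_names):
            p = fr.node_states[parent_of[b]]
            c = fr.node_states[b]
            if p == 0:
                at_risk[i, j] = True
                if c == 1:
                    gain[i, j] = True
    return branch_names, gain, at_risk


def randomization_test(
    observed_pairs: Sequence[PairKey],
    universe: Mapping[PairKey, FitchResult],
    tree: SpeciesTree,
    n_randomizations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """Empirical per-branch significance of the observed gain fractions.

    Each replicate draws |observed| pairs uniformly without replacement
    from the profiled universe and recomputes every branch's gain
    fraction from the (cached) parsimony reconstructions; the one-sided
    p is (1 + #replicates with fraction >= observed) / (n + 1).
    Branches whose observed fraction is undefined get p = NaN.
    """
    observed = [_pair(*p) for p in observed_pairs]
    missing = [p for p in observed if p not in universe]
    if missing:
        raise ValueError(f"observed pair(s) missing from universe: {missing[:3]}...")
    if len(observed) > len(universe):
        raise ValueError("observed set larger than the profiled universe")
    rng = np.random.default_rng(rng)
    keys = sorted(universe)
    recon = [universe[k] for k in keys]
    branch_names, gain, at_risk = _gain_arrays(tree, recon)
    idx_of = {k: i for i, k in enumerate(keys)}
    obs_idx = np.array([idx_of[p] for p in observed])
    obs_gain = gain[obs_idx].sum(axis=0)
    obs_risk = at_risk[obs_idx].sum(axis=0)
    with np.errstate(invalid="ignore"):
        obs_frac = np.where(obs_risk > 0, obs_gain / np.maximum(obs_risk, 1), np.nan)
    obs_frac[obs_risk == 0] = np.nan

    n_universe, k = len(keys), len(observed)
    exceed = np.zeros(len(branch_names), dtype=np.int64)
    for _ in range(n_randomizations):
        sample = rng.choice(n_universe, size=k, replace=False)
        g = gain[sample].sum(axis=0)
        r = at_risk[sample].sum(axis=0)
        frac = np.where(r > 0, g / np.maximum(r, 1), 0.0)
        exceed += frac >= np.nan_to_num(obs_frac, nan=np.inf)
    p = (1.0 + exceed) / (n_randomizations + 1.0)
    return {
        b: (float("nan") if np.isnan(obs_frac[j]) else float(p[j]))
        for j, b in enumerate(branch_names)
    }


# -- report ------------------------------------------------------------


def write_reconstruction_tsv(
    reconstructions: Mapping[PairKey, FitchResult],
    tree: SpeciesTree,
    path: str | Path,
) -> None:
    node_names = [n.name for n in tree.preorder()]
    lines = ["protein_a\tprotein_b\tscore\t" + "\t".join(node_names)]
    for pair in sorted(reconstructions):
        fr = reconstructions[pair]
        states = "\t".join(str(fr.node_states[n]) for n in node_names)
        lines.append(f"{pair[0]}\t{pair[1]}\t{fr.score}\t{states}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_run_manifest(path: str | Path, seed: int, config: Mapping) -> None:
    manifest = {"seed": seed, "config": dict(config)}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
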