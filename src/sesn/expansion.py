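"""Seed expansion with whole-network error correction.

One random seed per non-empty sub-network starts the predicted set K.
Each iteration then (1) adds, among all sub-network frontiers, the
candidate whose summed Wmatrix connection to K is largest, and (2) runs
an error-correction pass on the whole network: if the best frontier
protein by score_initial beats the weakest current member of K, the
former is added and the latter removed (each protein can be removed at
most once).  Expansion stops the moment |K| reaches the output length n;
proteins added earlier rank higher.

All argmax/argmin ties break toward the lexicographically smallest
protein ID, then the smallest sub-network index, so runs are fully
deterministic given the RNG seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sesn.expression import SubNetwork, SubNetworkSet
from sesn.io import PPINetwork
from sesn.weights import WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionConfig",
    "ExpansionState",
    "RankedPrediction",
    "init_seeds",
    "neighbor_frontier",
    "score_w",
    "select_expansion_node",
    "expansion_step",
    "error_correction_step",
    "run_expansion",
]

#: provenance labels
SEED = "seed"
EXPANSION = "sub-network expansion"
CORRECTION = "error-correction addition"


@dataclass
class ExpansionConfig:
    """Output length and run controls.

    Exactly one of `n` (absolute) or `n_fraction` (fraction of |V|,
    floored) fixes the output length; 1/4 and 1/10 are the common
    presets.  `strict_sync` forces K_i = K & V_i even for the initial
    seeds (default: seeds stay private to their own sub-network).
    """

    n: int | None = None
    n_fraction: float | None = None
    rng_seed: int = 0
    max_iterations: int = 10_000_000
    strict_sync: bool = False

    def resolve_n(self, n_nodes: int) -> int:
        if (self.n is None) == (self.n_fraction is None):
            raise ValueError("supply exactly one of n / n_fraction")
        if self.n is not None:
            n = int(self.n)
        else:
            n = int(np.floor(self.n_fraction * n_nodes))
        if n < 1 or n > n_nodes:
            raise ValueError(f"output length n={n} outside [1, {n_nodes}]")
        return n


@dataclass
class ExpansionState:
    """Mutable state of one expansion run."""

    K: list[str] = field(default_factory=list)          # addition order = rank
    K_set: set[str] = field(default_factory=set)
    K_i: list[set[str]] = field(default_factory=list)   # per sub-network
    removed: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[str, int]] = field(default_factory=dict)
    seed_of: dict[int, str] = field(default_factory=dict)
    step: int = 0

    def add(self, node: str, subnets: SubNetworkSet, label: str) -> None:
        if node in self.K_set:
            return
        self.K.append(node)
        self.K_set.add(node)
        for i, sn in enumerate(subnets):
            if node in sn.nodes:
                self.K_i[i].add(node)
        self.provenance[node] = (label, self.step)

    def remove(self, node: str) -> None:
        self.K.remove(node)
        self.K_set.discard(node)
        for ki in self.K_i:
            ki.discard(node)
        self.removed.add(node)
        self.provenance.pop(node, None)


@dataclass
class RankedPrediction:
    """Ordered prediction (earlier = higher rank) with provenance."""

    ranking: list[str]
    provenance: dict[str, tuple[str, int]]
    seeds: dict[int, str]
    removed: set[str]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.ranking)


def init_seeds(subnets: SubNetworkSet, config: ExpansionConfig) -> ExpansionState:
    """Draw one uniformly random seed per non-empty sub-network.

    Draws proceed in ascending sub-network index with a single seeded
    generator; a protein already seeded elsewhere is rejected, so the
    initial per-sub-network sets are pairwise disjoint.  A sub-network
    whose active nodes are all taken contributes no seed.
    """
    if all(not sn.nodes for sn in subnets):
        raise ValueError("cannot start expansion: every sub-network is empty")
    rng = np.random.default_rng(config.rng_seed)
    state = ExpansionState(K_i=[set() for _ in range(subnets.m)])
    chosen: set[str] = set()
    for i, sn in enumerate(subnets):
        pool = sorted(sn.nodes - chosen)
        if not pool:
            if sn.nodes:
                logger.warning("sub-network %d: all active proteins already "
                               "seeded; skipped", i)
            continue
        seed = pool[rng.integers(len(pool))]
        chosen.add(seed)
        state.K.append(seed)
        state.K_set.add(seed)
        state.K_i[i].add(seed)
        state.seed_of[i] = seed
        state.provenance[seed] = (SEED, 0)
    if config.strict_sync:
        for i, sn in enumerate(subnets):
            state.K_i[i] = state.K_set & sn.nodes
    return state


def neighbor_frontier(node_set: set[str], graph, exclude: set[str]) -> set[str]:
    """Union of the neighbor sets of `node_set`, minus `exclude`.

    `graph` is a whole network (Nei_K, exclude = K) or one sub-network
    (Nei_K_i, exclude = K).
    """
    out: set[str] = set()
    for u in node_set:
        out |= graph.neighbors(u)
    return out - exclude


def score_w(candidate: str, sub: SubNetwork, state: ExpansionState,
            weights: WeightModel) -> float:
    """Summed Wmatrix connection of a frontier candidate to K in one
    sub-network; pairs without an active edge contribute 0."""
    wm = weights.wmatrix[sub.index]
    total = 0.0
    for v in sub.neighbors(candidate) & state.K_set:
        key = (candidate, v) if candidate <= v else (v, candidate)
        total += wm.get(key, 0.0)
    return total


def select_expansion_node(state: ExpansionState, subnets: SubNetworkSet,
                          weights: WeightModel):
    """Two-step selection of the next expansion node.

    Step 1: in each sub-network take the frontier candidate with the
    largest score (ties -> smallest ID).  Step 2: take the global
    maximum over sub-networks (ties -> smallest ID, then smallest
    index).  Returns (protein, sub-network index) or None when every
    frontier is empty.
    """
    best = None  # (-score, node, index) minimized
    for i, sn in enumerate(subnets):
        frontier = neighbor_frontier(state.K_i[i], sn, state.K_set)
        for cand in frontier:
            entry = (-score_w(cand, sn, state, weights), cand, i)
            if best is None or entry < best:
                best = entry
    if best is None:
        return None
    return best[1], best[2]


def expansion_step(state: ExpansionState, subnets: SubNetworkSet,
                   weights: WeightModel) -> bool:
    """Add the selected node to K (and every K_i whose V_i holds it).
    Returns True if a node was added."""
    sel = select_expansion_node(state, subnets, weights)
    if sel is None:
        return False
    node, _ = sel
    state.add(node, subnets, EXPANSION)
    return True


def error_correction_step(state: ExpansionState, ppi: PPINetwork,
                          weights: WeightModel, subnets: SubNetworkSet,
                          stop_at: int | None = None) -> bool:
    """Whole-network correction pass.  Returns True if a node was added.

    Finds the weakest not-yet-removed member of K and the strongest
    whole-network frontier protein by score_initial.  On a strict win
    the latter is added; the former is then removed (once per protein
    ever) — unless the addition just reached `stop_at`, in which case
    the run is complete and no removal happens.
    """
    frontier = neighbor_frontier(state.K_set, ppi, state.K_set)
    if not frontier:
        return False
    si = weights.score_initial
    max_node = min(frontier, key=lambda v: (-si[v], v))
    removable = [v for v in state.K if v not in state.removed]
    if not removable:
        return False
    min_node = min(removable, key=lambda v: (si[v], v))
    if si[max_node] <= si[min_node]:
        return False
    state.add(max_node, subnets, CORRECTION)
    if stop_at is not None and len(state.K) >= stop_at:
        return True
    state.remove(min_node)
    return True


def run_expansion(ppi: PPINetwork, subnets: SubNetworkSet,
                  weights: WeightModel, config: ExpansionConfig,
                  use_correction: bool = True) -> RankedPrediction:
    """Full expansion loop: grow K to length n, alternating one
    sub-network expansion with one error-correction pass."""
    n = config.resolve_n(len(ppi))
    state = init_seeds(subnets, config)
    truncated = False
    iterations = 0
    while len(state.K) < n:
        iterations += 1
        if iterations > config.max_iterations:
            raise RuntimeError("run_expansion: max_iterations exceeded")
        state.step = iterations
        progressed = expansion_step(state, subnets, weights)
        if len(state.K) >= n:
            break
        if use_correction:
            progressed |= error_correction_step(state, ppi, weights, subnets,
                                                stop_at=n)
        if not progressed:
            truncated = True
            logger.warning("expansion stalled at |K|=%d < n=%d; no mechanism "
                           "can add a node", len(state.K), n)
            break
    ranking = state.K[:n]
    return RankedPrediction(ranking=ranking, provenance=dict(state.provenance),
                            seeds=dict(state.seed_of), removed=set(state.removed),
                            truncated=truncated)
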