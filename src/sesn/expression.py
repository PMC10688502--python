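"""Activity model and active PPI sub-network construction.

Raw expression columns are first averaged down to one value per sample
point (over cell cycles or over technical replicates).  Each gene then
gets k-sigma activity thresholds

    Thr_k = Avg + k * sigma * (1 - 1 / (1 + sigma^2)),   k in {1, 2, 3}

and a discretized per-sample activity probability Ap in
{0.0, 0.68, 0.95, 0.99} by threshold band.  One sub-network is built per
sample point: an interaction survives at sample i only if both endpoint
genes are actively expressed there (Ap_i > 0), weighted by the product of
the two activity probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sesn.io import PPINetwork, RawExpression, canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "AveragedExpression",
    "ActivityModel",
    "SubNetwork",
    "SubNetworkSet",
    "average_expression",
    "compute_thresholds",
    "compute_activity",
    "build_activity_model",
    "build_subnetworks",
    "AP_LEVELS",
]

#: discretized activity probabilities, from the normal-distribution
#: coverage of the 1-, 2- and 3-sigma intervals
AP_LEVELS = (0.0, 0.68, 0.95, 0.99)


@dataclass
class AveragedExpression:
    """Per-gene averaged expression series Ge_i(g), i = 0..n_samples-1."""

    ge: dict[str, np.ndarray]
    n_samples: int


@dataclass
class ActivityModel:
    """Per-gene mean, sigma, k-sigma thresholds and activity probabilities."""

    avg: dict[str, float]
    sigma: dict[str, float]
    thr: dict[str, tuple[float, float, float]]
    ap: dict[str, np.ndarray]
    n_samples: int

    def ap_of(self, gene: str, i: int) -> float:
        """Activity probability at sample i; genes without expression data
        are never active."""
        vec = self.ap.get(gene)
        return float(vec[i]) if vec is not None else 0.0


def average_expression(raw: RawExpression) -> AveragedExpression:
    """Collapse raw columns to one averaged value per sample point.

    cycles mode: Ge_i(g) = mean of expr at columns {i, i+P, i+2P, ...}
    over the cycles (P = points per cycle).  replicates mode: Ge_i(g) =
    mean of the i-th consecutive block of replicate columns.
    """
    plan = raw.sample_plan
    m = plan.n_samples
    ge: dict[str, np.ndarray] = {}
    for g, vec in raw.values.items():
        arr = np.asarray(vec, dtype=float)
        if plan.mode == "cycles":
            # columns laid out cycle-major: reshape to (cycles, points)
            ge[g] = arr.reshape(plan.cycles, plan.points).mean(axis=0)
        else:
            ge[g] = arr.reshape(plan.samples, plan.reps).mean(axis=1)
    return AveragedExpression(ge=ge, n_samples=m)


def compute_thresholds(ge_vector) -> tuple[float, float, float, float, float]:
    """Return (Avg, sigma, Thr_1, Thr_2, Thr_3) for one gene's Ge series.

    sigma uses the n-1 denominator.  The damping factor 1 - 1/(1+sigma^2)
    pulls the thresholds toward Avg for weakly fluctuating genes.
    """
    arr = np.asarray(ge_vector, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("threshold computation needs at least 2 sample points")
    avg = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    damp = 1.0 - 1.0 / (1.0 + sigma * sigma)
    thr = tuple(avg + k * sigma * damp for k in (1, 2, 3))
    return (avg, sigma) + thr


def compute_activity(ge_vector, thresholds) -> np.ndarray:
    """Map each averaged value to its activity probability band.

    thresholds: (Thr_1, Thr_2, Thr_3).  Bands evaluated top-down:
    Ge >= Thr_3 -> 0.99; Thr_3 > Ge >= Thr_2 -> 0.95;
    Thr_2 > Ge >= Thr_1 -> 0.68; Ge < Thr_1 -> 0.0.
    """
    thr1, thr2, thr3 = thresholds
    arr = np.asarray(ge_vector, dtype=float)
    ap = np.zeros_like(arr)
    ap[arr >= thr1] = 0.68
    ap[arr >= thr2] = 0.95
    ap[arr >= thr3] = 0.99
    return ap


def build_activity_model(avg_expr: AveragedExpression,
                         min_expression: float | None = None) -> ActivityModel:
    """Thresholds and activity probabilities for every gene.

    `min_expression` (default off) zeroes the activity of genes whose
    overall mean falls below the floor; otherwise a flat (sigma = 0) gene
    is literally always in the top band (Ge >= Thr_3 = Avg).
    """
    avg: dict[str, float] = {}
    sig: dict[str, float] = {}
    thr: dict[str, tuple[float, float, float]] = {}
    ap: dict[str, np.ndarray] = {}
    for g, vec in avg_expr.ge.items():
        a, s, t1, t2, t3 = compute_thresholds(vec)
        avg[g], sig[g], thr[g] = a, s, (t1, t2, t3)
        if min_expression is not None and a < min_expression:
            ap[g] = np.zeros(avg_expr.n_samples)
        else:
            ap[g] = compute_activity(vec, (t1, t2, t3))
    return ActivityModel(avg=avg, sigma=sig, thr=thr, ap=ap,
                         n_samples=avg_expr.n_samples)


@dataclass
class SubNetwork:
    """Active sub-network G_i = (V_i, E_i, W_i) at one sample point."""

    index: int
    nodes: set[str] = field(default_factory=set)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    adjacency: dict[str, set[str]] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.weights)

    def neighbors(self, v: str) -> set[str]:
        return self.adjacency.get(v, set())

    def weight(self, u: str, v: str) -> float:
        return self.weights.get(canonical_edge(u, v), 0.0)


@dataclass
class SubNetworkSet:
    """The family {G_1 .. G_m}, one sub-network per sample point."""

    subnetworks: list[SubNetwork]

    @property
    def m(self) -> int:
        return len(self.subnetworks)

    def __iter__(self):
        return iter(self.subnetworks)

    def __getitem__(self, i: int) -> SubNetwork:
        return self.subnetworks[i]


def build_subnetworks(ppi: PPINetwork, activity: ActivityModel) -> SubNetworkSet:
    """One sub-network per sample point.

    An edge (v, u) enters E_i iff both endpoints have Ap_i > 0, with
    weight Ap_i(v) * Ap_i(u).  V_i holds every node with Ap_i > 0 (so a
    seed may come from an isolated-but-active protein).  Proteins absent
    from the expression data have Ap = 0 everywhere and never appear.
    """
    m = activity.n_samples
    subs = [SubNetwork(index=i) for i in range(m)]
    node_list = sorted(ppi.nodes)
    ap = activity.ap
    for v in node_list:
        vec = ap.get(v)
        if vec is None:
            continue
        for i in range(m):
            if vec[i] > 0.0:
                subs[i].nodes.add(v)
    for u, v in ppi.edges:
        au, av = ap.get(u), ap.get(v)
        if au is None or av is None:
            continue
        key = canonical_edge(u, v)
        for i in range(m):
            if au[i] > 0.0 and av[i] > 0.0:
                sn = subs[i]
                sn.weights[key] = float(au[i] * av[i])
                sn.adjacency.setdefault(u, set()).add(v)
                sn.adjacency.setdefault(v, set()).add(u)
    n_empty = sum(1 for s in subs if not s.nodes)
    if n_empty:
        logger.info("build_subnetworks: %d of %d sub-networks are empty",
                    n_empty, m)
    return SubNetworkSet(subs)
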