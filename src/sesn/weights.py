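"""Biological weighting of nodes and edges.

Four evidence families feed the scores:

* GOW(v,u) = |GO_v & GO_u|^2 / (|GO_v| * |GO_u|) — GO-term overlap;
* GW(v,u)  = (PCC(Ge_v, Ge_u) + 1) / 2 — standardized co-expression;
* PCW(v,u) = PC_v * PC_u / PC_max^2 — complex-membership counts;
* SW_v     = SSC_v / SSC_max — selected-subcellular-compartment score.

The whole-network edge weight is W(v,u) = GOW * GW * PCW and a node's
score_initial is (sum of incident W) * SW_v.  Per sub-network, the
expansion weight matrix is

    Wmatrix_i(v,u) = GOW * Ap_i(v) * Ap_i(u) * PCW * SW_v * SW_u

(no co-expression factor).  Each factor carries an exponent alpha in
{0, 1}; a deleted factor (alpha = 0) is replaced by the constant 1, so an
evidence source can be ablated without annihilating the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sesn.expression import ActivityModel, AveragedExpression, SubNetworkSet
from sesn.io import AnnotationBundle, PPINetwork, canonical_edge

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHA_PRESETS",
    "STANDARD_COMPARTMENTS",
    "SubcellularScoring",
    "WeightModel",
    "go_weight",
    "pcc",
    "gene_weight",
    "complex_weight",
    "subcellular_scoring",
    "subcellular_weight",
    "edge_weight",
    "node_score_initial",
    "wmatrix_entry",
    "build_weight_model",
]

#: ablation exponent presets: (a1..a4) gate GOW/GW/PCW/SW inside
#: score_initial, (a5..a8) gate GOW/Ap/PCW/SW inside Wmatrix
ALPHA_PRESETS: dict[str, tuple[int, ...]] = {
    "all_ones": (1, 1, 1, 1, 1, 1, 1, 1),
    "yeast_best": (1, 1, 1, 1, 1, 1, 0, 1),
    "fly_best": (1, 1, 1, 0, 1, 1, 1, 1),
}

#: the eleven conventional compartment names of subcellular-localization databases
STANDARD_COMPARTMENTS = (
    "Nucleus", "Cytosol", "Cytoskeleton", "Peroxisome", "Vacuole",
    "Endoplasmic reticulum", "Golgi apparatus", "Plasma membrane",
    "Endosome", "Extracellular region", "Mitochondrion",
)

#: compartment set selected on the DIP reference data
SC_FIXED = frozenset({
    "Nucleus", "Cytosol", "Cytoskeleton",
    "Endoplasmic reticulum", "Golgi apparatus",
})


def _pow(base: float, alpha: int) -> float:
    """alpha-gated factor: alpha = 0 deletes the factor entirely (== 1)."""
    return base if alpha else 1.0


def go_weight(go_v: set[str], go_u: set[str]) -> float:
    """GO-overlap weight; 0 when either annotation set is empty."""
    if not go_v or not go_u:
        return 0.0
    inter = len(go_v & go_u)
    return inter * inter / (len(go_v) * len(go_u))


def pcc(x, y) -> float:
    """Sample Pearson correlation; 0 when either series has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pcc: series lengths differ")
    if x.size < 2:
        raise ValueError("pcc: need at least two sample points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((dx * dy).sum() / (sx * sy))


def gene_weight(x, y) -> float:
    """Co-expression weight: Pearson correlation rescaled to [0, 1]."""
    return (pcc(x, y) + 1.0) / 2.0


def complex_weight(pc_v: int, pc_u: int, pc_max: int) -> float:
    """Complex-membership weight; 0 when no complexes are supplied."""
    if pc_max == 0:
        return 0.0
    return (pc_v * pc_u) / (pc_max * pc_max)


@dataclass
class SubcellularScoring:
    """Compartment selection and scores.

    epi: per-compartment essential-protein proportion; ep_threshold: the
    dataset-level proportion used as selection cutoff; selected: the
    compartments whose EPI strictly exceeds the cutoff; scs: per selected
    compartment, protein count normalized by the largest.
    """

    epi: dict[str, float]
    ep_threshold: float
    selected: set[str]
    scs: dict[str, float]
    fallback_uniform: bool = False


def subcellular_scoring(
    subcellular: dict[str, set[str]],
    essentials: set[str],
    proteins: set[str],
    reference: tuple[int, int] | None = None,
    fixed_set: frozenset[str] | set[str] | None = None,
) -> SubcellularScoring:
    """Select essentiality-enriched compartments and score them.

    EPI_c = (#essential proteins annotated to c) / (#proteins annotated
    to c); the cutoff is ep/p computed either on an external reference
    pair ``reference=(ep, p)`` or on this dataset.  ``fixed_set`` pins the
    selection to a given compartment set instead.  A compartment is
    scored by its protein count relative to the largest selected one.
    """
    comp_proteins: dict[str, set[str]] = {}
    for v, comps in subcellular.items():
        if v not in proteins:
            continue
        for c in comps:
            comp_proteins.setdefault(c, set()).add(v)
    epi = {c: (len(members & essentials) / len(members)) if members else 0.0
           for c, members in comp_proteins.items()}
    if reference is not None:
        ep, p = reference
        thr = ep / p if p else 0.0
    else:
        thr = (len(essentials & proteins) / len(proteins)) if proteins else 0.0

    if fixed_set is not None:
        selected = set(fixed_set) & set(comp_proteins)
    else:
        selected = {c for c, v in epi.items() if v > thr}

    fallback = False
    scs: dict[str, float] = {}
    if selected:
        nsc = {c: len(comp_proteins[c]) for c in selected}
        nsc_max = max(nsc.values())
        scs = {c: n / nsc_max for c, n in nsc.items()}
    else:
        logger.warning("subcellular_scoring: no compartment selected; "
                       "subcellular weights fall back to 1.0")
        fallback = True
    return SubcellularScoring(epi=epi, ep_threshold=thr, selected=selected,
                              scs=scs, fallback_uniform=fallback)


def subcellular_weight(protein: str, scoring: SubcellularScoring,
                       subcellular: dict[str, set[str]],
                       ssc_max: float) -> float:
    """SW_v = SSC_v / SSC_max; 0 when SSC_max = 0."""
    if scoring.fallback_uniform:
        return 1.0
    if ssc_max == 0.0:
        return 0.0
    ssc = sum(scoring.scs[c]
              for c in subcellular.get(protein, set()) & scoring.selected)
    return ssc / ssc_max


def edge_weight(gow: float, gw: float, pcw: float,
                alpha: tuple[int, ...]) -> float:
    """Whole-network edge weight W(v,u), alpha-gated."""
    return _pow(gow, alpha[0]) * _pow(gw, alpha[1]) * _pow(pcw, alpha[2])


def node_score_initial(edge_sum: float, sw_v: float,
                       alpha: tuple[int, ...]) -> float:
    """score_initial_v = (sum of incident edge weights) * SW_v, alpha-gated."""
    return edge_sum * _pow(sw_v, alpha[3])


def wmatrix_entry(gow: float, ap_v: float, ap_u: float, pcw: float,
                  sw_v: float, sw_u: float, alpha: tuple[int, ...]) -> float:
    """Per-sub-network expansion weight, alpha-gated; no co-expression term."""
    return (_pow(gow, alpha[4]) * _pow(ap_v * ap_u, alpha[5])
            * _pow(pcw, alpha[6]) * _pow(sw_v * sw_u, alpha[7]))


@dataclass
class WeightModel:
    """All precomputed weights for one network + annotation + activity set."""

    alpha: tuple[int, ...]
    gow: dict[tuple[str, str], float] = field(default_factory=dict)
    gw: dict[tuple[str, str], float] = field(default_factory=dict)
    pcw: dict[tuple[str, str], float] = field(default_factory=dict)
    sw: dict[str, float] = field(default_factory=dict)
    w_edge: dict[tuple[str, str], float] = field(default_factory=dict)
    score_initial: dict[str, float] = field(default_factory=dict)
    wmatrix: list[dict[tuple[str, str], float]] = field(default_factory=list)
    scoring: SubcellularScoring | None = None

    def wmatrix_of(self, i: int, u: str, v: str) -> float:
        return self.wmatrix[i].get(canonical_edge(u, v), 0.0)


def resolve_alpha(alpha=None, alpha_preset: str | None = None) -> tuple[int, ...]:
    if alpha is not None and alpha_preset is not None:
        raise ValueError("give either alpha or alpha_preset, not both")
    if alpha_preset is not None:
        try:
            return ALPHA_PRESETS[alpha_preset]
        except KeyError:
            raise ValueError(f"unknown alpha preset {alpha_preset!r}") from None
    if alpha is None:
        return ALPHA_PRESETS["all_ones"]
    alpha = tuple(int(a) for a in alpha)
    if len(alpha) != 8 or any(a not in (0, 1) for a in alpha):
        raise ValueError("alpha must be eight 0/1 exponents")
    return alpha


def build_weight_model(
    ppi: PPINetwork,
    bundle: AnnotationBundle,
    avg_expr: AveragedExpression,
    activity: ActivityModel,
    subnets: SubNetworkSet,
    alpha=None,
    alpha_preset: str | None = None,
    subcellular_reference: tuple[int, int] | None = None,
    subcellular_fixed_set=None,
) -> WeightModel:
    """Precompute every weight table used by seed expansion.

    ``subcellular_reference``: optional external (ep, p) pair for the
    compartment-selection cutoff (default: computed on this dataset).
    ``subcellular_fixed_set``: pin the selected compartments instead.
    """
    alpha = resolve_alpha(alpha, alpha_preset)
    nodes = ppi.nodes
    model = WeightModel(alpha=alpha)

    # complex-membership counts over the network
    pc = {v: 0 for v in nodes}
    for cplx in bundle.complexes:
        for v in cplx:
            if v in pc:
                pc[v] += 1
    pc_max = max(pc.values(), default=0)

    # subcellular selection and per-node SW
    scoring = subcellular_scoring(
        bundle.subcellular, bundle.essentials, nodes,
        reference=subcellular_reference, fixed_set=subcellular_fixed_set,
    )
    model.scoring = scoring
    if scoring.fallback_uniform:
        model.sw = {v: 1.0 for v in nodes}
    else:
        ssc = {v: sum(scoring.scs[c] for c in
                      bundle.compartments_of(v) & scoring.selected)
               for v in nodes}
        ssc_max = max(ssc.values(), default=0.0)
        if ssc_max == 0.0:
            model.sw = {v: 0.0 for v in nodes}
        else:
            model.sw = {v: s / ssc_max for v, s in ssc.items()}

    # per-edge families and the whole-network weight
    ge = avg_expr.ge
    for key in ppi.edges:
        u, v = key
        gow = go_weight(bundle.go_of(u), bundle.go_of(v))
        if u in ge and v in ge:
            gw = gene_weight(ge[u], ge[v])
        else:
            gw = 0.5  # no co-expression information
        pcw = complex_weight(pc[u], pc[v], pc_max)
        model.gow[key] = gow
        model.gw[key] = gw
        model.pcw[key] = pcw
        model.w_edge[key] = edge_weight(gow, gw, pcw, alpha)

    for v in nodes:
        s = sum(model.w_edge[canonical_edge(v, u)] for u in ppi.neighbors(v))
        model.score_initial[v] = node_score_initial(s, model.sw[v], alpha)

    # per-sub-network expansion weights on the active edges
    for sn in subnets:
        entry: dict[tuple[str, str], float] = {}
        for key in sn.weights:
            u, v = key
            entry[key] = wmatrix_entry(
                model.gow[key], activity.ap_of(u, sn.index),
                activity.ap_of(v, sn.index), model.pcw[key],
                model.sw[u], model.sw[v], alpha,
            )
        model.wmatrix.append(entry)
    return model
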