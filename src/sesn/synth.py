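"""Synthetic benchmark generator.

Emits a self-contained dataset — PPI network, raw expression matrix,
GO/complex/subcellular annotations and a planted essential-protein gold
standard — with the statistical structure the method assumes: essentials
form a denser sub-community, share a periodic co-expression signal
(mimicking a cell-cycle time course), carry more complex memberships and
more overlapping GO terms, and are enriched in a subset of compartments.
Everything is deterministic given the RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from sesn.io import (
    AnnotationBundle,
    PPINetwork,
    RawExpression,
    SamplePlan,
    write_annotations,
    write_expression,
    write_ppi,
)
from sesn.weights import STANDARD_COMPARTMENTS

__all__ = ["SyntheticConfig", "generate", "write_dataset"]


def _default_compartments() -> dict[str, float]:
    # enrichment factor > 1: essentials over-represented (nucleus-like);
    # < 1: under-represented (peroxisome-like)
    factors = (3.0, 2.5, 2.0, 0.3, 0.8, 1.5, 1.5, 0.9, 0.8, 0.3, 1.0)
    return dict(zip(STANDARD_COMPARTMENTS, factors))


@dataclass
class SyntheticConfig:
    """Knobs of the generated world.

    Defaults give a yeast-flavoured miniature: 200 proteins, 15 %
    essential, a 12-point x 3-cycle expression layout, and moderate noise
    on the shared periodic signal of the essential module.
    """

    n_proteins: int = 200
    mean_degree: float = 8.0
    essential_fraction: float = 0.15
    sample_plan: SamplePlan = field(
        default_factory=lambda: SamplePlan.cycles_plan(12, 3))
    n_go_terms: int = 60
    n_complexes: int = 30
    compartments: dict[str, float] = field(default_factory=_default_compartments)
    co_expression_strength: float = 0.8
    noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 4:
            raise ValueError("n_proteins must be at least 4")
        if not (0.0 < self.essential_fraction < 1.0):
            raise ValueError("essential_fraction must lie in (0, 1)")
        if not (0.0 <= self.co_expression_strength <= 1.0):
            raise ValueError("co_expression_strength must lie in [0, 1]")
        if self.mean_degree >= self.n_proteins:
            raise ValueError("mean_degree must be below n_proteins")
        if self.mean_degree < 2 or self.n_go_terms < 1 or self.n_complexes < 0:
            raise ValueError("infeasible synthetic configuration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _protein_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate(config: SyntheticConfig) -> tuple[PPINetwork, RawExpression,
                                               AnnotationBundle]:
    """Generate one dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(config.rng_seed)
    ids = _protein_ids(config.n_proteins)
    n_ess = round(config.n_proteins * config.essential_fraction)
    ess_idx = rng.choice(config.n_proteins, size=n_ess, replace=False)
    essentials = {ids[i] for i in ess_idx}

    net = _make_network(config, rng, ids, essentials)
    raw = _make_expression(config, rng, ids, essentials)
    bundle = _make_annotations(config, rng, ids, essentials)
    return net, raw, bundle


def _make_network(config: SyntheticConfig, rng, ids, essentials) -> PPINetwork:
    n = config.n_proteins
    m_attach = max(1, int(round(config.mean_degree / 2)))
    g = nx.barabasi_albert_graph(n, m_attach,
                                 seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(g, dict(enumerate(ids)))
    # densify the planted module: extra mutual edges among essentials
    ess = sorted(essentials)
    p_extra = min(1.0, 3.0 * config.mean_degree / n)
    for a in range(len(ess)):
        for b in range(a + 1, len(ess)):
            if rng.random() < p_extra:
                graph.add_edge(ess[a], ess[b])
    return PPINetwork(graph)


def _make_expression(config: SyntheticConfig, rng, ids, essentials) -> RawExpression:
    plan = config.sample_plan
    m = plan.n_samples
    baseline = 5.0
    amplitude = 2.0  # vs noise_sd: roughly half of essential samples active
    shared = np.sin(2.0 * math.pi * np.arange(m) / m)
    s = config.co_expression_strength
    values: dict[str, list[float]] = {}
    for g in ids:
        base = baseline + rng.normal(0.0, 0.5)
        if g in essentials:
            own = np.sin(2.0 * math.pi * (np.arange(m) / m + rng.random()))
            signal = amplitude * (s * shared + (1.0 - s) * own)
        else:
            own = np.sin(2.0 * math.pi * (np.arange(m) / m + rng.random()))
            signal = amplitude * own
        per_sample = base + signal
        cols = np.empty(plan.n_columns)
        if plan.mode == "cycles":
            for c in range(plan.cycles):
                cols[c * plan.points:(c + 1) * plan.points] = (
                    per_sample + rng.normal(0.0, config.noise_sd, size=m))
        else:
            for i in range(plan.samples):
                cols[i * plan.reps:(i + 1) * plan.reps] = (
                    per_sample[i] + rng.normal(0.0, config.noise_sd,
                                               size=plan.reps))
        values[g] = [float(max(x, 0.0)) for x in cols]
    return RawExpression(values=values, sample_plan=plan)


def _make_annotations(config: SyntheticConfig, rng, ids, essentials
                      ) -> AnnotationBundle:
    n_terms = config.n_go_terms
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    core = terms[:max(1, n_terms // 6)]  # shared functional core of the module
    go: dict[str, set[str]] = {}
    for g in ids:
        if g in essentials:
            k_core = min(len(core), 1 + int(rng.integers(4)))
            k_rest = int(rng.integers(3))
            picks = set(rng.choice(len(core), size=k_core, replace=False))
            chosen = {core[i] for i in picks}
            if k_rest:
                chosen |= {terms[i] for i in
                           rng.choice(n_terms, size=k_rest, replace=False)}
        else:
            k = 1 + int(rng.integers(4))
            chosen = {terms[i] for i in
                      rng.choice(n_terms, size=k, replace=False)}
        go[g] = chosen

    ess_sorted = sorted(essentials)
    non_ess = sorted(set(ids) - essentials)
    complexes: list[set[str]] = []
    for _ in range(config.n_complexes):
        size = 2 + int(rng.integers(5))
        n_from_ess = min(len(ess_sorted), int(np.ceil(size * 0.6)))
        members = {ess_sorted[i] for i in
                   rng.choice(len(ess_sorted), size=n_from_ess, replace=False)}
        n_rest = size - len(members)
        if n_rest > 0 and non_ess:
            members |= {non_ess[i] for i in
                        rng.choice(len(non_ess), size=min(n_rest, len(non_ess)),
                                   replace=False)}
        if len(members) >= 2:
            complexes.append(members)

    comp_names = sorted(config.compartments)
    base_p = {c: 0.25 for c in comp_names}
    subcellular: dict[str, set[str]] = {}
    for g in ids:
        comps = set()
        for c in comp_names:
            p = base_p[c] * (config.compartments[c] if g in essentials else 1.0)
            if rng.random() < min(p, 0.95):
                comps.add(c)
        if not comps:  # everybody lives somewhere
            comps.add(comp_names[int(rng.integers(len(comp_names)))])
        subcellular[g] = comps

    return AnnotationBundle(go_terms=go, complexes=complexes,
                            subcellular=subcellular, essentials=set(essentials))


def write_dataset(dataset: tuple[PPINetwork, RawExpression, AnnotationBundle],
                  directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the plain-text formats the readers consume."""
    net, raw, bundle = dataset
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": d / "ppi.tsv",
        "expression": d / "expression.tsv",
        "go": d / "go.tsv",
        "complexes": d / "complexes.txt",
        "subcellular": d / "subcellular.tsv",
        "essentials": d / "essentials.txt",
    }
    write_ppi(net, paths["ppi"])
    write_expression(raw, paths["expression"])
    write_annotations(bundle, paths["go"], paths["complexes"],
                      paths["subcellular"], paths["essentials"])
    return paths
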