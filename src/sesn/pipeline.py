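"""End-to-end orchestration: read -> sub-networks -> weights -> expansion
-> evaluation, plus the ablation sweep and component-removal variants.

Variants:

* ``sesn`` — the full method;
* ``rm_sub`` — expansion on the whole network as one pseudo sub-network
  with every activity probability set to 1;
* ``rm_correction`` — the error-correction mechanism is skipped;
* ``wmatrix_only`` — no expansion: proteins ranked by their summed
  incident Wmatrix weight (aggregated over sub-networks);
* ``score_initial_only`` — no expansion: proteins ranked by their
  whole-network score_initial;
* ``all_subcellular`` — compartment selection disabled (every observed
  compartment is kept and scored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from sesn.evaluation import JackknifeCurve, Measures, confusion, jackknife, measures
from sesn.expansion import ExpansionConfig, RankedPrediction, run_expansion
from sesn.expression import (
    ActivityModel,
    AveragedExpression,
    average_expression,
    build_activity_model,
    build_subnetworks,
)
from sesn.io import (
    AnnotationBundle,
    PPINetwork,
    RawExpression,
    SamplePlan,
    apply_mapping,
    read_annotations,
    read_expression,
    read_mapping,
    read_ppi,
)
from sesn.weights import (
    SC_FIXED,
    WeightModel,
    build_weight_model,
    resolve_alpha,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "VARIANTS", "PipelineResult", "DEFAULT_SWEEP",
           "run_pipeline", "run_pipeline_on_data", "run_ablation_sweep"]

VARIANTS = ("sesn", "rm_sub", "rm_correction", "wmatrix_only",
            "score_initial_only", "all_subcellular")

#: the nine ablation exponent vectors: each position zeroed in turn,
#: then the all-ones identity row
DEFAULT_SWEEP: tuple[tuple[int, ...], ...] = tuple(
    tuple(0 if j == i else 1 for j in range(8)) for i in range(8)
) + ((1,) * 8,)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    ppi_path: str | None = None
    expression_path: str | None = None
    go_path: str | None = None
    complex_path: str | None = None
    subcell_path: str | None = None
    essential_path: str | None = None
    mapping_path: str | None = None
    sample_plan: SamplePlan | dict | None = None
    alpha: Sequence[int] | None = None
    alpha_preset: str | None = None
    subcellular_reference: tuple[int, int] | None = None
    subcellular_fixed: bool = False
    n: int | None = None
    n_fraction: float | None = 0.25
    rng_seed: int = 0
    variant: str = "sesn"
    min_expression: float | None = None
    strict_sync: bool = False

    def resolved_plan(self) -> SamplePlan:
        if isinstance(self.sample_plan, SamplePlan):
            return self.sample_plan
        if isinstance(self.sample_plan, dict):
            return SamplePlan.from_dict(self.sample_plan)
        raise ValueError("a sample plan is required")


@dataclass
class PipelineResult:
    prediction: RankedPrediction
    measures: Measures
    jackknife: JackknifeCurve
    weights: WeightModel
    universe: set[str] = field(default_factory=set)


def _rank_by_score(scores: dict[str, float], n: int) -> list[str]:
    """Descending score, lexicographic tie-break."""
    return sorted(scores, key=lambda v: (-scores[v], v))[:n]


def _uniform_activity(ppi: PPINetwork) -> ActivityModel:
    """Pseudo activity model: one sample point, every protein active with
    probability 1 (used by the rm_sub variant)."""
    ones = {v: np.ones(1) for v in ppi.nodes}
    return ActivityModel(avg={}, sigma={}, thr={}, ap=ones, n_samples=1)


def run_pipeline_on_data(
    ppi: PPINetwork,
    raw: RawExpression,
    bundle: AnnotationBundle,
    config: RunConfig,
) -> PipelineResult:
    """Run one variant on in-memory data."""
    if config.variant not in VARIANTS:
        raise ValueError(f"unknown variant {config.variant!r}; "
                         f"expected one of {VARIANTS}")

    avg_expr = average_expression(raw)
    activity = build_activity_model(avg_expr, config.min_expression)

    if config.variant == "rm_sub":
        act_for_subnets = _uniform_activity(ppi)
    else:
        act_for_subnets = activity
    subnets = build_subnetworks(ppi, act_for_subnets)

    weights = build_weight_model(
        ppi, bundle, avg_expr, act_for_subnets, subnets,
        alpha=config.alpha, alpha_preset=config.alpha_preset,
        subcellular_reference=config.subcellular_reference,
        subcellular_fixed_set=(
            SC_FIXED if config.subcellular_fixed
            else (_all_compartments(bundle)
                  if config.variant == "all_subcellular" else None)),
    )

    n_nodes = len(ppi)
    exp_cfg = ExpansionConfig(n=config.n, n_fraction=config.n_fraction,
                              rng_seed=config.rng_seed,
                              strict_sync=config.strict_sync)
    n = exp_cfg.resolve_n(n_nodes)

    if config.variant == "wmatrix_only":
        scores = {v: 0.0 for v in ppi.nodes}
        for wm in weights.wmatrix:
            for (u, v), w in wm.items():
                scores[u] += w
                scores[v] += w
        ranking = _rank_by_score(scores, n)
        prediction = RankedPrediction(
            ranking=ranking,
            provenance={v: ("wmatrix score", i) for i, v in enumerate(ranking)},
            seeds={}, removed=set())
    elif config.variant == "score_initial_only":
        ranking = _rank_by_score(weights.score_initial, n)
        prediction = RankedPrediction(
            ranking=ranking,
            provenance={v: ("score_initial", i) for i, v in enumerate(ranking)},
            seeds={}, removed=set())
    else:
        prediction = run_expansion(
            ppi, subnets, weights, exp_cfg,
            use_correction=(config.variant != "rm_correction"))

    universe = ppi.nodes
    c = confusion(prediction, bundle.essentials, universe)
    return PipelineResult(
        prediction=prediction,
        measures=measures(c),
        jackknife=jackknife(prediction, bundle.essentials),
        weights=weights,
        universe=universe,
    )


def _all_compartments(bundle: AnnotationBundle) -> set[str]:
    out: set[str] = set()
    for comps in bundle.subcellular.values():
        out |= comps
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read the input files named in `config` and run one variant."""
    ppi = read_ppi(config.ppi_path)
    raw = read_expression(config.expression_path, config.resolved_plan())
    bundle = read_annotations(config.go_path, config.complex_path,
                              config.subcell_path, config.essential_path)
    if config.mapping_path:
        mapping = read_mapping(config.mapping_path)
        ppi = apply_mapping(ppi, mapping)
        raw = apply_mapping(raw, mapping)
        bundle = apply_mapping(bundle, mapping)
    return run_pipeline_on_data(ppi, raw, bundle, config)


def run_ablation_sweep(
    ppi: PPINetwork,
    raw: RawExpression,
    bundle: AnnotationBundle,
    config: RunConfig,
    alpha_sets: Sequence[Sequence[int]] = DEFAULT_SWEEP,
) -> list[tuple[tuple[int, ...], PipelineResult]]:
    """One pipeline run per exponent vector, all else (incl. seed) fixed."""
    out = []
    for alpha in alpha_sets:
        cfg = RunConfig(**{**config.__dict__,
                           "alpha": resolve_alpha(alpha),
                           "alpha_preset": None})
        out.append((resolve_alpha(alpha),
                    run_pipeline_on_data(ppi, raw, bundle, cfg)))
    return out


def write_result(result: PipelineResult, directory: str | Path) -> None:
    """Write ranking TSV, metrics JSON and jackknife TSV."""
    import json

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "ranking.tsv", "w", encoding="utf-8") as fh:
        fh.write("rank\tprotein_id\tprovenance\tstep\n")
        for r, v in enumerate(result.prediction.ranking, start=1):
            label, step = result.prediction.provenance.get(v, ("?", -1))
            fh.write(f"{r}\t{v}\t{label}\t{step}\n")
    with open(d / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(result.measures.as_dict(), fh, indent=2)
        fh.write("\n")
    with open(d / "jackknife.tsv", "w", encoding="utf-8") as fh:
        fh.write("rank\tcumulative_tp\n")
        for r, tp in enumerate(result.jackknife.cumulative_tp, start=1):
            fh.write(f"{r}\t{tp}\n")
    with open(d / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump({
            "seeds": {str(k): v for k, v in result.prediction.seeds.items()},
            "removed": sorted(result.prediction.removed),
            "truncated": result.prediction.truncated,
            "n": len(result.prediction.ranking),
        }, fh, indent=2)
        fh.write("\n")
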