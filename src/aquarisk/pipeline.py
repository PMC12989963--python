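"""End-to-end orchestration of the analysis stages.

``run_pipeline`` wires the stages together for a dataset already in
memory (typically a :class:`~aquarisk.synthetic.SyntheticDataset` or
tables loaded through :mod:`aquarisk.io`): flow tallies, contamination
and concentration estimates, food loss, health risk, and — when budgets
and a baseline allocation are given — scheme evaluation, optimization,
and the scheme comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import StudyConfig
from .flows import (
    ConcentrationTable,
    ContaminationMatrix,
    estimate_concentration,
    estimate_contamination,
    fit_diversity_regression,
    summarize_streams,
    tally_flow_counts,
)
from .food_loss import TradeVolumeTable, compute_food_loss, compute_trade_volume
from .health_risk import RiskTable, compute_chq_hi, compute_edi, compute_hq, flag_exceedances
from .monitoring import (
    AllocationMatrix,
    OptimizationResult,
    SchemeComparison,
    SchemeEvaluation,
    compare_schemes,
    evaluate_scheme,
    optimize_allocation,
)
from .types import STREAM_EXTERNAL, STREAM_UNKNOWN


@dataclass
class PipelineResult:
    counts: object
    matrix: ContaminationMatrix
    concentration: ConcentrationTable
    streams: pd.DataFrame
    diversity: dict
    loss: TradeVolumeTable
    risk: RiskTable
    exceedances: pd.DataFrame
    baseline_eval: SchemeEvaluation | None = None
    optimization: OptimizationResult | None = None
    optimized_eval: SchemeEvaluation | None = None
    comparison: SchemeComparison | None = None


def run_pipeline(
    records,
    trade,
    consumption,
    reference,
    config: StudyConfig,
    budgets: dict[str, int] | None = None,
    baseline_alloc: AllocationMatrix | None = None,
    solver: str = "exact_dp",
) -> PipelineResult:
    counts = tally_flow_counts(records, years=config.year_range)
    matrix = estimate_contamination(counts, config.unknown_label)
    cl = estimate_concentration(records)
    streams = summarize_streams(matrix)
    diversity = {}
    for stream in (STREAM_EXTERNAL, STREAM_UNKNOWN):
        try:
            diversity[stream] = fit_diversity_regression(matrix, stream)
        except ValueError:
            diversity[stream] = None

    tv = compute_trade_volume(trade)
    loss = compute_food_loss(tv, counts)

    edi = compute_edi(cl, consumption, config.body_weight)
    hq = compute_hq(edi, reference)
    risk = compute_chq_hi(hq, matrix, config.standard_value)
    exceed = flag_exceedances(risk)

    baseline_eval = optimization = optimized_eval = comparison = None
    if baseline_alloc is not None:
        baseline_eval = evaluate_scheme(baseline_alloc, matrix, risk, loss, config)
    if budgets is not None:
        optimization = optimize_allocation(matrix, risk, trade, budgets, config,
                                           solver=solver)
        optimized_eval = evaluate_scheme(optimization.allocation, matrix, risk,
                                         loss, config)
        if baseline_eval is not None:
            comparison = compare_schemes(optimized_eval, baseline_eval)

    return PipelineResult(
        counts=counts, matrix=matrix, concentration=cl, streams=streams,
        diversity=diversity, loss=loss, risk=risk, exceedances=exceed,
        baseline_eval=baseline_eval, optimization=optimization,
        optimized_eval=optimized_eval, comparison=comparison,
    )
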