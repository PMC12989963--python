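"""One-at-a-time deterministic sensitivity scenarios.

Each scenario multiplies the estimated contamination probabilities
and/or mean concentrations by a fixed factor (probabilities are clipped
back into [0, 1], with clip events logged) and optionally lowers the
assay sensitivity, then re-runs every downstream stage: hazard indices,
food loss, and the optimized-versus-baseline monitoring advantage.
The identity scenario (all factors 1) reproduces the baseline outputs
bit-exactly because no arithmetic is applied at all.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import StudyConfig
from .flows import ConcentrationTable, ContaminationMatrix
from .food_loss import annual_average_loss, compute_food_loss, compute_trade_volume
from .health_risk import compute_chq_hi, compute_edi, compute_hq, flag_exceedances
from .monitoring import (
    AllocationMatrix,
    compare_schemes,
    evaluate_scheme,
    optimize_allocation,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One perturbation of the estimated inputs."""

    label: str
    contamination_multiplier: float = 1.0
    concentration_multiplier: float = 1.0
    detection_sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if self.contamination_multiplier <= 0 or self.concentration_multiplier <= 0:
            raise ValueError("multipliers must be > 0")


def default_scenarios() -> list[ScenarioSpec]:
    """The standard grid: baseline, ±10 % contamination, ±20 % concentration,
    98 % assay sensitivity, and the two combined corner scenarios."""
    return [
        ScenarioSpec("baseline"),
        ScenarioSpec("contamination-10pct", contamination_multiplier=0.9),
        ScenarioSpec("contamination+10pct", contamination_multiplier=1.1),
        ScenarioSpec("concentration-20pct", concentration_multiplier=0.8),
        ScenarioSpec("concentration+20pct", concentration_multiplier=1.2),
        ScenarioSpec("assay-sensitivity-98pct", detection_sensitivity=0.98),
        ScenarioSpec("both-up", contamination_multiplier=1.1,
                     concentration_multiplier=1.2),
        ScenarioSpec("both-down", contamination_multiplier=0.9,
                     concentration_multiplier=0.8),
    ]


def perturb_matrix(matrix: ContaminationMatrix, factor: float) -> ContaminationMatrix:
    """Scale every contamination probability, clipping into [0, 1]."""
    if factor == 1.0:
        return matrix
    cells = matrix.cells.copy()
    probc = matrix.probc.copy()
    marg = matrix.marginals.copy()
    clipped = 0
    for df, cols in ((cells, ["a", "a_ant"]), (probc, ["probc"]), (marg, ["a", "a_ant"])):
        for col in cols:
            scaled = df[col] * factor
            clipped += int((scaled > 1.0).sum())
            df[col] = np.minimum(scaled, 1.0)
    if clipped:
        logger.warning("clipped %d perturbed probabilities at 1", clipped)
    return ContaminationMatrix(cells, probc, marg, matrix.unknown_label)


def perturb_concentration(cl: ConcentrationTable, factor: float) -> ConcentrationTable:
    if factor == 1.0:
        return cl
    table = cl.table.copy()
    table["cl"] = table["cl"] * factor
    return ConcentrationTable(table)


@dataclass
class SensitivityReport:
    scenarios: list[ScenarioSpec]
    hi: pd.DataFrame              # monitor x scenario hazard indices
    loss: pd.DataFrame            # monitor x scenario mean annual AR loss
    advantage: pd.DataFrame | None  # scenario, monitor, delta_stv, delta_shi
    exceedances: dict[str, list[str]] = field(default_factory=dict)


def run_scenarios(
    matrix: ContaminationMatrix,
    cl: ConcentrationTable,
    trade,
    consumption,
    reference,
    config: StudyConfig,
    budgets: dict[str, int] | None = None,
    baseline_alloc: AllocationMatrix | None = None,
    scenarios: list[ScenarioSpec] | None = None,
) -> SensitivityReport:
    """Recompute risk, loss, and the optimizer advantage per scenario.

    The scheme comparison is run only when a baseline allocation and
    budgets are supplied.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    if len(scenarios) == 0:
        raise ValueError("need at least one scenario")

    from .flows import tally_flow_counts  # local import to avoid cycle confusion

    tv = compute_trade_volume(trade)
    hi_cols = {}
    loss_cols = {}
    adv_rows = []
    exceed = {}
    for sc in scenarios:
        m = perturb_matrix(matrix, sc.contamination_multiplier)
        c = perturb_concentration(cl, sc.concentration_multiplier)
        cfg = config.replace(detection_sensitivity=sc.detection_sensitivity)

        edi = compute_edi(c, consumption, cfg.body_weight)
        hq = compute_hq(edi, reference)
        risk = compute_chq_hi(hq, m, cfg.standard_value)
        hi_cols[sc.label] = risk.hi.set_index("monitoring_province")["HI"]
        exceed[sc.label] = list(flag_exceedances(risk)["monitoring_province"])

        # Food loss from the perturbed destination rates.
        vol = tv.copy()
        rates = m.marginals.set_index("monitoring_province")
        vol["rate_all"] = vol["province"].map(rates["a"])
        vol["rate_ant"] = vol["province"].map(rates["a_ant"])
        vol["CTV_all"] = vol["TV"] * vol["rate_all"]
        vol["CTV_ant"] = vol["TV"] * vol["rate_ant"]
        loss_cols[sc.label] = vol.groupby("province")["CTV_ant"].mean()

        if baseline_alloc is not None and budgets is not None:
            from .food_loss import TradeVolumeTable
            loss_table = TradeVolumeTable(
                vol[["province", "year", "TV", "rate_all", "rate_ant",
                     "CTV_all", "CTV_ant"]],
                pd.DataFrame(columns=["province", "year", "hazard_name", "rate", "CTV"]),
            )
            base_eval = evaluate_scheme(baseline_alloc, m, risk, loss_table, cfg)
            opt = optimize_allocation(m, risk, trade, budgets, cfg)
            opt_eval = evaluate_scheme(opt.allocation, m, risk, loss_table, cfg)
            comp = compare_schemes(opt_eval, base_eval)
            for row in comp.table.itertuples():
                adv_rows.append((sc.label, row.monitoring_province,
                                 row.delta_stv, row.delta_stv_intercepted,
                                 row.delta_shi))

    hi = pd.DataFrame(hi_cols)
    loss = pd.DataFrame(loss_cols)
    advantage = (
        pd.DataFrame(adv_rows, columns=["scenario", "monitoring_province",
                                        "delta_stv", "delta_stv_intercepted",
                                        "delta_shi"])
        if adv_rows else None
    )
    return SensitivityReport(list(scenarios), hi, loss, advantage, exceed)


def rank_stability(report: SensitivityReport, k: int) -> dict:
    """Stability of the top-k risk ranking and of the optimizer advantage.

    Compares each scenario's top-k HI province set with the first
    (baseline) scenario: Jaccard overlap and an exact-set indicator,
    plus the fraction of provinces whose optimizer advantage keeps the
    baseline sign in every scenario.
    """
    if len(report.scenarios) < 2:
        raise ValueError("need >= 2 scenarios to assess stability")
    n_prov = len(report.hi.index)
    if k > n_prov:
        raise ValueError(f"k={k} exceeds the {n_prov} provinces available")

    base_label = report.scenarios[0].label
    def topk(label):
        return set(report.hi[label].nlargest(k).index)

    base_set = topk(base_label)
    rows = []
    for sc in report.scenarios:
        s = topk(sc.label)
        jaccard = len(s & base_set) / len(s | base_set)
        rows.append((sc.label, jaccard, s == base_set))
    table = pd.DataFrame(rows, columns=["scenario", "topk_jaccard", "topk_exact"])

    sign_stable = None
    if report.advantage is not None:
        adv = report.advantage.pivot(index="monitoring_province", columns="scenario",
                                     values="delta_shi")
        base_sign = np.sign(adv[base_label])
        stable = (np.sign(adv).eq(base_sign, axis=0)).all(axis=1)
        sign_stable = float(stable.mean())
    return {
        "table": table,
        "all_topk_exact": bool(table["topk_exact"].all()),
        "min_jaccard": float(table["topk_jaccard"].min()),
        "advantage_sign_stability": sign_stable,
    }


def build_report(stages: dict, out_dir) -> list:
    """Write the flat-file report bundle; missing stages are listed as gaps.

    Expected keys: concentration, streams, diversity, food_loss, risk,
    allocation, sensitivity.  Each value is a DataFrame (or an object
    exposing one) written as CSV; absent keys are recorded in the
    manifest's ``gaps`` section.
    """
    import json
    from pathlib import Path

    expected = ["concentration", "streams", "diversity", "food_loss", "risk",
                "allocation", "sensitivity"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    gaps = []
    for key in expected:
        obj = stages.get(key)
        if obj is None:
            gaps.append(key)
            continue
        df = obj if isinstance(obj, pd.DataFrame) else getattr(obj, "table", None)
        if df is None:
            gaps.append(key)
            continue
        path = out / f"report_{key}.csv"
        df.to_csv(path, index=bool(df.index.name or isinstance(df.index, pd.MultiIndex)))
        written.append(path)
    manifest = out / "report_manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"sections": [str(p.name) for p in written], "gaps": gaps}, fh, indent=2)
    written.append(manifest)
    return written
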