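"""Source-resolved contamination estimation.

For every flow (source province *i* -> monitoring province *j*) the
sampling records yield counts

* ``NST`` — total samples tested on the flow,
* ``NSC`` — samples with at least one hazard exceedance,
* ``NSC_ant`` — samples with at least one *antibiotic* exceedance,
* ``NSC_h`` — per-hazard counts (a sample counts once per distinct
  hazard it exceeds, so a two-hazard sample contributes twice to the
  occurrence total but once to ``NSC``).

The per-antibiotic contamination probability is the conditional
decomposition

    ProbC(i, j, k) = (NSC / NST) * (NSC_k / sum_h NSC_h)

i.e. the flow's overall failure rate times hazard *k*'s share of hazard
occurrences, so the per-hazard probabilities partition the contaminated
mass exactly.  Mean exceedance concentrations are pooled over all
sources per monitoring province, reflecting the assumption that
destination-level means represent the blend of all suppliers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import records_to_frame, validate_sampling_frame
from .config import StudyConfig
from .types import (
    ANTIBIOTIC,
    STREAM_EXTERNAL,
    STREAM_INTERNAL,
    STREAM_UNKNOWN,
    STREAMS,
    UNKNOWN,
    SamplingRecord,
    source_stream,
)

logger = logging.getLogger(__name__)

_FLOW_KEY = ["source_province", "monitoring_province"]


def as_sampling_frame(records, config: StudyConfig | None = None) -> pd.DataFrame:
    """Accept either a long-format DataFrame or a list of records."""
    if isinstance(records, pd.DataFrame):
        if config is not None:
            return validate_sampling_frame(records, config)
        return records
    return records_to_frame(records)


@dataclass
class FlowCounts:
    """Per-flow sample counts pooled over a year window."""

    table: pd.DataFrame          # index (source, monitor): NST, NSC, NSC_ant
    hazard_counts: pd.DataFrame  # columns: source, monitor, hazard_name, hazard_class, count
    years: tuple[int, int] | None = None

    def total(self) -> pd.DataFrame:
        return self.table.groupby("monitoring_province").sum()


def tally_flow_counts(
    records,
    years: tuple[int, int] | None = None,
    hazard_filter: str | None = None,
) -> FlowCounts:
    """Tally per-flow totals, failures, and per-hazard occurrence counts.

    ``hazard_filter`` restricts the per-hazard table to one hazard class
    (the sample-level NST/NSC/NSC_ant columns are unaffected).
    """
    df = as_sampling_frame(records)
    if years is not None:
        lo, hi = years
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if df.empty:
        empty = pd.DataFrame(columns=["NST", "NSC", "NSC_ant"],
                             index=pd.MultiIndex.from_arrays([[], []], names=_FLOW_KEY))
        hz = pd.DataFrame(columns=_FLOW_KEY + ["hazard_name", "hazard_class", "count"])
        return FlowCounts(empty, hz, years)

    samples = df.drop_duplicates("sample_id")
    viol = df[(df["result"] == "fail") & df["hazard_name"].notna()]
    viol = viol.drop_duplicates(["sample_id", "hazard_name"])

    nst = samples.groupby(_FLOW_KEY).size().rename("NST")
    failed = samples[samples["result"] == "fail"]
    nsc = failed.groupby(_FLOW_KEY).size().rename("NSC")
    ant_ids = viol.loc[viol["hazard_class"] == ANTIBIOTIC, "sample_id"].unique()
    nsc_ant = (
        failed[failed["sample_id"].isin(set(ant_ids))]
        .groupby(_FLOW_KEY).size().rename("NSC_ant")
    )
    table = pd.concat([nst, nsc, nsc_ant], axis=1).fillna(0).astype(int)

    if hazard_filter is not None:
        viol = viol[viol["hazard_class"] == hazard_filter]
    hazard_counts = (
        viol.groupby(_FLOW_KEY + ["hazard_name", "hazard_class"])
        .size().rename("count").reset_index()
    )
    return FlowCounts(table, hazard_counts, years)


def sum_counts(parts: Iterable[FlowCounts]) -> FlowCounts:
    """Add per-period tallies; integer-exact, so pooling order is irrelevant."""
    parts = list(parts)
    table = sum(p.table.reindex(
        pd.MultiIndex.from_tuples(
            sorted(set().union(*(p.table.index for p in parts))), names=_FLOW_KEY),
        fill_value=0) for p in parts)
    hz = pd.concat([p.hazard_counts for p in parts], ignore_index=True)
    hz = (hz.groupby(_FLOW_KEY + ["hazard_name", "hazard_class"])["count"]
            .sum().reset_index())
    years = None
    spans = [p.years for p in parts if p.years is not None]
    if spans:
        years = (min(s[0] for s in spans), max(s[1] for s in spans))
    return FlowCounts(table.astype(int), hz, years)


@dataclass
class ContaminationMatrix:
    """Estimated per-flow contamination rates and per-antibiotic decomposition."""

    cells: pd.DataFrame      # source, monitor, NST, NSC, NSC_ant, a, a_ant, source_category
    probc: pd.DataFrame      # source, monitor, hazard_name, hazard_class, probc
    marginals: pd.DataFrame  # monitor, NST, NSC, NSC_ant, a, a_ant
    unknown_label: str = UNKNOWN

    def get_probc(self, source: str, monitor: str, hazard: str) -> float:
        sel = self.probc[
            (self.probc["source_province"] == source)
            & (self.probc["monitoring_province"] == monitor)
            & (self.probc["hazard_name"] == hazard)
        ]
        return float(sel["probc"].iloc[0]) if len(sel) else 0.0


def estimate_contamination(
    counts: FlowCounts, unknown_label: str = UNKNOWN
) -> ContaminationMatrix:
    """Turn flow counts into rate estimates.

    Flows with ``NST == 0`` are treated as missing (excluded, with a
    warning) rather than as zero rates; an untested flow carries no
    information.
    """
    table = counts.table.reset_index()
    zero = table["NST"] == 0
    if (zero & (table["NSC"] > 0)).any():
        raise ValueError("inconsistent counts: NSC > 0 with NST == 0")
    if zero.any():
        logger.warning("%d flow cell(s) with no samples excluded from estimates",
                       int(zero.sum()))
        table = table[~zero]

    cells = table.copy()
    cells["a"] = cells["NSC"] / cells["NST"]
    cells["a_ant"] = cells["NSC_ant"] / cells["NST"]
    cells["source_category"] = [
        source_stream(s, m, unknown_label)
        for s, m in zip(cells["source_province"], cells["monitoring_province"])
    ]

    hz = counts.hazard_counts.merge(
        cells[_FLOW_KEY + ["NST", "NSC"]], on=_FLOW_KEY, how="inner"
    )
    denom = hz.groupby(_FLOW_KEY)["count"].transform("sum")
    hz["probc"] = (hz["NSC"] / hz["NST"]) * (hz["count"] / denom)
    probc = hz[_FLOW_KEY + ["hazard_name", "hazard_class", "count", "probc"]]

    marg = cells.groupby("monitoring_province")[["NST", "NSC", "NSC_ant"]].sum()
    marg["a"] = marg["NSC"] / marg["NST"]
    marg["a_ant"] = marg["NSC_ant"] / marg["NST"]
    marg = marg.reset_index()
    return ContaminationMatrix(cells, probc, marg, unknown_label)


@dataclass
class ConcentrationTable:
    """Mean exceedance concentration per (monitoring province, hazard)."""

    table: pd.DataFrame  # monitoring_province, hazard_name, hazard_class, cl, n_contributing

    def get_cl(self, monitor: str, hazard: str) -> float | None:
        sel = self.table[
            (self.table["monitoring_province"] == monitor)
            & (self.table["hazard_name"] == hazard)
        ]
        return float(sel["cl"].iloc[0]) if len(sel) else None


def estimate_concentration(records) -> ConcentrationTable:
    """Average measured concentration per destination and hazard.

    Pooled over all sources: each contaminated sample contributes its
    measured level once per distinct hazard it exceeds.
    """
    df = as_sampling_frame(records)
    viol = df[(df["result"] == "fail") & df["hazard_name"].notna()]
    viol = viol.drop_duplicates(["sample_id", "hazard_name"])
    if viol.empty:
        return ConcentrationTable(pd.DataFrame(
            columns=["monitoring_province", "hazard_name", "hazard_class",
                     "cl", "n_contributing"]))
    grouped = viol.groupby(["monitoring_province", "hazard_name", "hazard_class"])
    out = grouped["concentration_ug_per_kg"].agg(cl="mean", n_contributing="size")
    out = out.reset_index()
    out["n_contributing"] = out["n_contributing"].astype(int)
    return ConcentrationTable(out)


@dataclass
class DiversityRegression:
    """OLS fit of a stream's per-province contamination rate on source diversity."""

    stream: str
    slope: float
    intercept: float
    r_squared: float
    ci95_slope: tuple[float, float]
    n_points: int


def fit_diversity_line(x: Sequence[float], y: Sequence[float], stream: str = "") -> DiversityRegression:
    """Ordinary-least-squares line through (diversity, rate) points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for the diversity regression, got {len(x)}")
    if np.ptp(y) == 0.0:
        # Degenerate flat response: slope 0 with no explanatory power.
        return DiversityRegression(stream, 0.0, float(y[0]), 0.0, (0.0, 0.0), len(x))
    if np.ptp(x) == 0.0:
        raise ValueError("source diversity is constant across provinces; "
                         "the regression is underdetermined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return DiversityRegression(
        stream=stream,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        ci95_slope=(float(ci[1][0]), float(ci[1][1])),
        n_points=len(x),
    )


def diversity_points(matrix: ContaminationMatrix, stream: str) -> pd.DataFrame:
    """Per-monitor (source diversity, pooled stream antibiotic rate) points.

    Diversity counts the distinct traceable (non-unknown) source
    provinces observed for the monitor in the pooled window.
    """
    cells = matrix.cells
    traceable = cells[cells["source_category"] != STREAM_UNKNOWN]
    n_sources = traceable.groupby("monitoring_province")["source_province"].nunique()
    sub = cells[cells["source_category"] == stream]
    grouped = sub.groupby("monitoring_province")[["NSC_ant", "NST"]].sum()
    rate = (grouped["NSC_ant"] / grouped["NST"]).rename("rate")
    points = pd.concat([n_sources.rename("n_sources"), rate], axis=1, join="inner")
    return points.dropna().reset_index()


def fit_diversity_regression(matrix: ContaminationMatrix, stream: str) -> DiversityRegression:
    """Fit stream rate against traceable source diversity, pooled per province."""
    if stream not in (STREAM_EXTERNAL, STREAM_UNKNOWN):
        raise ValueError(f"stream must be external or unknown, got {stream!r}")
    points = diversity_points(matrix, stream)
    return fit_diversity_line(points["n_sources"], points["rate"], stream)


def summarize_streams(matrix: ContaminationMatrix, weighted: bool = False) -> pd.DataFrame:
    """Mean contamination probability per source stream.

    Default is the unweighted mean over defined flow cells; ``weighted``
    weights cells by their sample counts instead.
    """
    cells = matrix.cells
    rows = []
    for stream in STREAMS:
        sub = cells[cells["source_category"] == stream]
        if sub.empty:
            logger.warning("no defined cells for stream %s", stream)
            rows.append((stream, np.nan, np.nan, 0))
            continue
        if weighted:
            w = sub["NST"].to_numpy(dtype=float)
            mean_ant = float(np.average(sub["a_ant"], weights=w))
            mean_all = float(np.average(sub["a"], weights=w))
        else:
            mean_ant = float(sub["a_ant"].mean())
            mean_all = float(sub["a"].mean())
        rows.append((stream, mean_ant, mean_all, len(sub)))
    return pd.DataFrame(rows, columns=["stream", "mean_a_ant", "mean_a", "n_cells"])
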