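"""Contamination-attributable food loss.

Net trade volume per province-year is ``TV = PV - EV + IV`` (production
minus exports plus imports, tons).  The loss attributable to
contamination is that volume times the destination's pooled failure
rate; the antibiotic-specific loss uses the per-antibiotic sample rate.
Because one sample can exceed several antibiotics, the per-antibiotic
losses can sum to more than the deduplicated "any antibiotic" loss; the
headline figure uses the deduplicated rate and the per-compound
decomposition is reported separately.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flows import FlowCounts
from .io import trade_to_frame
from .types import ANTIBIOTIC, TradeRecord

logger = logging.getLogger(__name__)


def compute_trade_volume(trade) -> pd.DataFrame:
    """Net trade volume per (province, year); rejects negative volumes."""
    if not isinstance(trade, pd.DataFrame):
        trade = trade_to_frame(list(trade))
    df = trade.copy()
    df["TV"] = df["production_tons"] - df["export_tons"] + df["import_tons"]
    neg = df[df["TV"] < 0]
    if len(neg):
        keys = list(neg[["province", "year"]].itertuples(index=False, name=None))
        raise ValueError(f"negative net trade volume for: {keys}")
    return df[["province", "year", "production_tons", "export_tons", "import_tons", "TV"]]


@dataclass
class TradeVolumeTable:
    """Per province-year trade volume with attributable losses."""

    volumes: pd.DataFrame        # province, year, TV, rate_all, rate_ant, CTV_all, CTV_ant
    per_antibiotic: pd.DataFrame  # province, year, hazard_name, rate, CTV

    def annual_mean_ctv_ant(self) -> pd.Series:
        """Mean annual antibiotic-attributable loss per province (tons)."""
        return self.volumes.groupby("province")["CTV_ant"].mean()


def _pooled_rates(counts: FlowCounts) -> pd.DataFrame:
    pooled = counts.table.groupby("monitoring_province")[["NST", "NSC", "NSC_ant"]].sum()
    pooled["rate_all"] = pooled["NSC"] / pooled["NST"]
    pooled["rate_ant"] = pooled["NSC_ant"] / pooled["NST"]
    return pooled


def _pooled_hazard_rates(counts: FlowCounts) -> pd.DataFrame:
    hz = counts.hazard_counts
    hz = hz[hz["hazard_class"] == ANTIBIOTIC]
    per_k = hz.groupby(["monitoring_province", "hazard_name"])["count"].sum().reset_index()
    nst = counts.table.groupby("monitoring_province")["NST"].sum().rename("NST")
    per_k = per_k.merge(nst, on="monitoring_province")
    per_k["rate"] = per_k["count"] / per_k["NST"]
    return per_k[["monitoring_province", "hazard_name", "rate"]]


def compute_food_loss(
    tv: pd.DataFrame,
    counts: FlowCounts,
    counts_by_year: dict[int, FlowCounts] | None = None,
) -> TradeVolumeTable:
    """Apply destination-pooled contamination rates to trade volumes.

    Default applies the pooled-window rates to each year's volume;
    passing ``counts_by_year`` switches to that year's own rates.
    """
    def rates_for(year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        if counts_by_year is not None and year in counts_by_year:
            c = counts_by_year[year]
            return _pooled_rates(c), _pooled_hazard_rates(c)
        return pooled, hazard_rates

    pooled = _pooled_rates(counts)
    hazard_rates = _pooled_hazard_rates(counts)

    vol_rows = []
    ab_rows = []
    missing: set[str] = set()
    for row in tv.itertuples():
        rates, hz = rates_for(int(row.year))
        if row.province not in rates.index:
            missing.add(row.province)
            vol_rows.append((row.province, row.year, row.TV,
                             np.nan, np.nan, np.nan, np.nan))
            continue
        r = rates.loc[row.province]
        vol_rows.append((
            row.province, row.year, row.TV,
            r["rate_all"], r["rate_ant"],
            row.TV * r["rate_all"], row.TV * r["rate_ant"],
        ))
        sub = hz[hz["monitoring_province"] == row.province]
        for hz_row in sub.itertuples():
            ab_rows.append((row.province, row.year, hz_row.hazard_name,
                            hz_row.rate, row.TV * hz_row.rate))
    if missing:
        logger.warning("no sampling counts for province(s) %s; losses left missing",
                       sorted(missing))
    volumes = pd.DataFrame(
        vol_rows,
        columns=["province", "year", "TV", "rate_all", "rate_ant", "CTV_all", "CTV_ant"],
    )
    per_ab = pd.DataFrame(
        ab_rows, columns=["province", "year", "hazard_name", "rate", "CTV"]
    )
    return TradeVolumeTable(volumes, per_ab)


def annual_average_loss(
    table: TradeVolumeTable,
    scope: str = "antibiotic",
    per_antibiotic_sum: bool = False,
    national: bool = False,
):
    """Mean annual loss per province (tons), optionally averaged nationally.

    ``scope='antibiotic'`` uses the deduplicated any-antibiotic loss (or
    the per-compound sum when ``per_antibiotic_sum``); ``scope='all'``
    uses the all-contaminant loss.
    """
    if scope == "antibiotic":
        if per_antibiotic_sum:
            per_year = (table.per_antibiotic.groupby(["province", "year"])["CTV"].sum())
            per_province = per_year.groupby("province").mean()
        else:
            per_province = table.volumes.groupby("province")["CTV_ant"].mean()
    elif scope == "all":
        per_province = table.volumes.groupby("province")["CTV_all"].mean()
    else:
        raise ValueError(f"scope must be 'antibiotic' or 'all', got {scope!r}")
    if national:
        return float(per_province.mean())
    return per_province
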