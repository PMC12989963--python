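"""Dietary exposure and cumulative health risk.

The chain is the standard veterinary-residue assessment:

* ``EDI = CL * DI / BW`` — estimated daily intake of antibiotic *k* in a
  province (ug/kg-bw/day), from the mean exceedance concentration CL
  (ug/kg), the daily aquatic intake DI (kg/person/day), and adult body
  weight BW (kg);
* ``HQ = EDI / ADI`` — hazard quotient against the acceptable daily
  intake;
* ``CHQ = ProbC * HQ`` — the quotient corrected by the conditional
  probability that a product on flow (i, j) actually carries residue k;
* ``HI_j = sum over sources and antibiotics of CHQ`` — the cumulative
  hazard index, flagged when it exceeds the standard value (1).

Everything is exactly linear in the concentrations, which is the
backbone of the +/-20 % concentration sensitivity scenario.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .flows import ConcentrationTable, ContaminationMatrix
from .io import consumption_to_frame, reference_to_frame
from .types import ANTIBIOTIC

logger = logging.getLogger(__name__)


def compute_edi(
    cl: ConcentrationTable,
    consumption,
    body_weight: float,
) -> pd.DataFrame:
    """Estimated daily intake per (antibiotic, monitoring province).

    Daily intake per province is averaged over the reported years.
    Raises if a province with measured concentrations has no consumption
    data.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if not isinstance(consumption, pd.DataFrame):
        consumption = consumption_to_frame(list(consumption))
    di = consumption.groupby("province")["daily_intake_kg_per_person_day"].mean()

    table = cl.table.copy()
    needed = set(table["monitoring_province"].unique())
    missing = sorted(needed - set(di.index))
    if missing:
        raise ValueError(f"no consumption data for province(s): {missing}")
    table["di"] = table["monitoring_province"].map(di)
    table["edi"] = table["cl"] * table["di"] / body_weight
    return table[["monitoring_province", "hazard_name", "hazard_class",
                  "cl", "di", "edi", "n_contributing"]]


def compute_hq(edi: pd.DataFrame, reference) -> pd.DataFrame:
    """Hazard quotient EDI/ADI per (antibiotic, province).

    Hazards without a usable ADI (missing from the reference table, or
    with a blank ADI) are excluded with a warning and listed nowhere
    else downstream.
    """
    if not isinstance(reference, pd.DataFrame):
        reference = reference_to_frame(list(reference))
    ref = reference.rename(columns={"antibiotic": "hazard_name",
                                    "adi_ug_per_kg_bw_day": "adi"})
    if (ref["adi"].dropna() <= 0).any():
        bad = ref.loc[ref["adi"] <= 0, "hazard_name"].tolist()
        raise ValueError(f"non-positive ADI for: {bad}")

    ant = edi[edi["hazard_class"] == ANTIBIOTIC].copy()
    merged = ant.merge(ref[["hazard_name", "adi"]], on="hazard_name", how="left")
    dropped = sorted(merged.loc[merged["adi"].isna(), "hazard_name"].unique())
    if dropped:
        logger.warning("excluding antibiotic(s) without ADI from hazard quotients: %s",
                       dropped)
    merged = merged.dropna(subset=["adi"]).copy()
    merged["hq"] = merged["edi"] / merged["adi"]
    merged.attrs["dropped_antibiotics"] = dropped
    return merged[["monitoring_province", "hazard_name", "cl", "di", "edi", "adi", "hq"]]


@dataclass
class RiskTable:
    """Hazard-index decomposition per province.

    ``chq`` holds the full (antibiotic, source, monitor) decomposition;
    ``hi_partial`` its per-source sums (needed by the saved-health-risk
    evaluation); ``hi`` the per-province totals with exceedance flags.
    """

    chq: pd.DataFrame         # source, monitor, hazard_name, probc, hq, chq
    hi_partial: pd.DataFrame  # source, monitor, hi_partial
    hi: pd.DataFrame          # monitor, HI, exceeds_standard
    standard_value: float = 1.0


def compute_chq_hi(
    hq: pd.DataFrame,
    matrix: ContaminationMatrix,
    standard_value: float = 1.0,
) -> RiskTable:
    """Probability-corrected quotients and the per-province hazard index."""
    probc = matrix.probc[matrix.probc["hazard_class"] == ANTIBIOTIC]
    merged = probc.merge(
        hq[["monitoring_province", "hazard_name", "hq"]],
        on=["monitoring_province", "hazard_name"],
        how="inner",
    ).copy()
    merged["chq"] = merged["probc"] * merged["hq"]
    chq = merged[["source_province", "monitoring_province", "hazard_name",
                  "probc", "hq", "chq"]]

    hi_partial = (
        chq.groupby(["source_province", "monitoring_province"])["chq"]
        .sum().rename("hi_partial").reset_index()
    )
    monitors = matrix.marginals["monitoring_province"]
    hi = (
        chq.groupby("monitoring_province")["chq"].sum()
        .reindex(monitors, fill_value=0.0)
        .rename("HI").reset_index()
    )
    hi["exceeds_standard"] = hi["HI"] > standard_value
    return RiskTable(chq, hi_partial, hi, standard_value)


def flag_exceedances(risk: RiskTable, standard_value: float | None = None) -> pd.DataFrame:
    """Provinces whose hazard index exceeds the standard, sorted descending."""
    threshold = risk.standard_value if standard_value is None else standard_value
    out = risk.hi[risk.hi["HI"] > threshold].sort_values("HI", ascending=False)
    return out.reset_index(drop=True)
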