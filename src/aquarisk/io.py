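"""Readers and writers for the tabular interchange formats.

The canonical sampling schema is *long format*: one CSV row per
sample x violation.  Pass rows appear once with empty hazard fields;
fail rows appear once per hazard exceedance.  The other tables (trade,
consumption, antibiotic reference, province roster) are plain one-row-
per-key CSVs.

Internally the pipeline operates on pandas DataFrames in these same
schemas; :func:`frame_to_records` / :func:`records_to_frame` convert
between the frame form and the typed record objects.
"""
from __future__ import annotations

import datetime
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import StudyConfig
from .types import (
    ANTIBIOTIC,
    HAZARD_CLASSES,
    AntibioticReference,
    ConsumptionRecord,
    SamplingRecord,
    SchemaError,
    TradeRecord,
    Violation,
)

logger = logging.getLogger(__name__)

SAMPLING_COLUMNS = [
    "sample_id",
    "year",
    "monitoring_province",
    "source_province",
    "product_category",
    "result",
    "hazard_name",
    "hazard_class",
    "concentration_ug_per_kg",
    "limit_ug_per_kg",
]

TRADE_COLUMNS = ["province", "year", "production_tons", "export_tons", "import_tons"]
CONSUMPTION_COLUMNS = ["province", "year", "daily_intake_kg_per_person_day"]
REFERENCE_COLUMNS = ["antibiotic", "adi_ug_per_kg_bw_day", "mrl_ug_per_kg"]
PROVINCE_COLUMNS = ["code", "name"]


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


# ---------------------------------------------------------------------------
# sampling records
# ---------------------------------------------------------------------------

def validate_sampling_frame(df: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Validate and normalise a long-format sampling table in place.

    Blank source provinces become the unknown sentinel; years are checked
    against the configured window; province codes are checked against the
    roster when one is configured.
    """
    missing = [c for c in SAMPLING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sampling table missing columns: {missing}")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["sample_id"] = df["sample_id"].astype(str)
    df["monitoring_province"] = df["monitoring_province"].astype(str)
    df["source_province"] = df["source_province"].where(
        ~df["source_province"].map(_is_blank), config.unknown_label
    ).astype(str)

    lo, hi = config.year_range
    bad_years = df.loc[(df["year"] < lo) | (df["year"] > hi), "year"].unique()
    if len(bad_years):
        raise SchemaError(
            f"years outside configured range [{lo}, {hi}]: {sorted(bad_years.tolist())}"
        )

    bad_result = set(df["result"].unique()) - {"pass", "fail"}
    if bad_result:
        raise SchemaError(f"result column must be pass|fail, found {sorted(bad_result)}")

    if config.provinces is not None:
        roster = set(config.provinces)
        bad_mon = sorted(set(df["monitoring_province"]) - roster)
        bad_src = sorted(set(df["source_province"]) - roster - {config.unknown_label})
        if bad_mon or bad_src:
            raise SchemaError(
                f"unknown province codes — monitoring: {bad_mon}, source: {bad_src}"
            )

    fail = df["result"] == "fail"
    blank_hazard = df["hazard_name"].map(_is_blank)
    offenders = df.loc[fail & blank_hazard, "sample_id"].unique()
    if len(offenders):
        raise SchemaError(
            f"failed rows without hazard fields for sample_id(s): {sorted(offenders.tolist())}"
        )
    stray = df.loc[~fail & ~blank_hazard, "sample_id"].unique()
    if len(stray):
        raise SchemaError(
            f"pass rows carrying hazard fields for sample_id(s): {sorted(stray.tolist())}"
        )
    bad_class = set(df.loc[fail, "hazard_class"].unique()) - set(HAZARD_CLASSES)
    if bad_class:
        raise SchemaError(f"unknown hazard_class values: {sorted(bad_class)}")
    return df


def frame_to_records(df: pd.DataFrame, config: StudyConfig) -> list[SamplingRecord]:
    """Merge long-format rows into :class:`SamplingRecord` objects.

    Rows sharing a ``sample_id`` are merged; the result is ordered by
    (year, monitoring_province, sample_id), so the output is independent
    of the input row order.
    """
    df = validate_sampling_frame(df, config)
    records: list[SamplingRecord] = []
    attr_cols = ["year", "monitoring_province", "source_province", "product_category", "result"]
    for sample_id, group in df.groupby("sample_id", sort=False):
        attrs = group[attr_cols].drop_duplicates()
        if len(attrs) > 1:
            raise SchemaError(
                f"sample {sample_id!r}: rows disagree on sample-level attributes"
            )
        row = attrs.iloc[0]
        violations: list[Violation] = []
        if row["result"] == "fail":
            for _, vrow in group.sort_values("hazard_name").iterrows():
                violations.append(
                    Violation(
                        hazard_name=str(vrow["hazard_name"]),
                        hazard_class=str(vrow["hazard_class"]),
                        concentration=float(vrow["concentration_ug_per_kg"]),
                        limit=float(vrow["limit_ug_per_kg"]),
                    )
                )
        records.append(
            SamplingRecord(
                sample_id=str(sample_id),
                year=int(row["year"]),
                monitoring_province=str(row["monitoring_province"]),
                source_province=str(row["source_province"]),
                product_category=str(row["product_category"]),
                passed=row["result"] == "pass",
                violations=tuple(violations),
            )
        )
    records.sort(key=lambda r: (r.year, r.monitoring_province, r.sample_id))
    return records


def records_to_frame(records: Iterable[SamplingRecord]) -> pd.DataFrame:
    """Serialize records back to the canonical long-format table."""
    rows = []
    for rec in records:
        base = {
            "sample_id": rec.sample_id,
            "year": rec.year,
            "monitoring_province": rec.monitoring_province,
            "source_province": rec.source_province,
            "product_category": rec.product_category,
            "result": "pass" if rec.passed else "fail",
        }
        if rec.passed:
            rows.append({**base, "hazard_name": None, "hazard_class": None,
                         "concentration_ug_per_kg": None, "limit_ug_per_kg": None})
        else:
            for v in rec.violations:
                rows.append({**base, "hazard_name": v.hazard_name,
                             "hazard_class": v.hazard_class,
                             "concentration_ug_per_kg": v.concentration,
                             "limit_ug_per_kg": v.limit})
    return pd.DataFrame(rows, columns=SAMPLING_COLUMNS)


def read_sampling_records(path: str | Path, config: StudyConfig) -> list[SamplingRecord]:
    """Read a long-format sampling CSV into merged, ordered records."""
    df = pd.read_csv(path, dtype={"sample_id": str, "monitoring_province": str,
                                  "source_province": str, "hazard_name": str,
                                  "hazard_class": str})
    return frame_to_records(df, config)


# ---------------------------------------------------------------------------
# support tables
# ---------------------------------------------------------------------------

def _reject_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        offenders = df.loc[dup, keys].to_records(index=False).tolist()
        raise SchemaError(f"duplicate {what} keys: {offenders}")


def read_trade(path: str | Path) -> list[TradeRecord]:
    df = pd.read_csv(path, dtype={"province": str})
    missing = [c for c in TRADE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trade table missing columns: {missing}")
    _reject_duplicates(df, ["province", "year"], "trade (province, year)")
    return [
        TradeRecord(str(r.province), int(r.year), float(r.production_tons),
                    float(r.export_tons), float(r.import_tons))
        for r in df.itertuples()
    ]


def read_consumption(path: str | Path) -> list[ConsumptionRecord]:
    df = pd.read_csv(path, dtype={"province": str})
    missing = [c for c in CONSUMPTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"consumption table missing columns: {missing}")
    _reject_duplicates(df, ["province", "year"], "consumption (province, year)")
    return [
        ConsumptionRecord(str(r.province), int(r.year),
                          float(r.daily_intake_kg_per_person_day))
        for r in df.itertuples()
    ]


def read_reference(path: str | Path) -> list[AntibioticReference]:
    df = pd.read_csv(path, dtype={"antibiotic": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reference table missing columns: {missing}")
    _reject_duplicates(df, ["antibiotic"], "antibiotic reference")
    out = []
    for r in df.itertuples():
        adi = None if _is_blank(r.adi_ug_per_kg_bw_day) else float(r.adi_ug_per_kg_bw_day)
        if adi is None:
            logger.warning("antibiotic %s has no ADI; it will be excluded from "
                           "hazard quotients", r.antibiotic)
        out.append(AntibioticReference(str(r.antibiotic), adi, float(r.mrl_ug_per_kg)))
    return out


def read_support_tables(
    trade_path: str | Path,
    consumption_path: str | Path,
    reference_path: str | Path,
) -> tuple[list[TradeRecord], list[ConsumptionRecord], list[AntibioticReference]]:
    return read_trade(trade_path), read_consumption(consumption_path), read_reference(reference_path)


def read_provinces(path: str | Path) -> tuple[str, ...]:
    df = pd.read_csv(path, dtype=str)
    if "code" not in df.columns:
        raise SchemaError("province roster needs a 'code' column")
    return tuple(df["code"].astype(str))


# ---------------------------------------------------------------------------
# typed lists -> frames (for pipeline stages that prefer frames)
# ---------------------------------------------------------------------------

def trade_to_frame(trade: Sequence[TradeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.province, t.year, t.production, t.export, t.import_) for t in trade],
        columns=TRADE_COLUMNS,
    )


def consumption_to_frame(consumption: Sequence[ConsumptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.province, c.year, c.daily_intake) for c in consumption],
        columns=CONSUMPTION_COLUMNS,
    )


def reference_to_frame(reference: Sequence[AntibioticReference]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.antibiotic, r.adi, r.mrl) for r in reference],
        columns=REFERENCE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: StudyConfig | None = None,
) -> list[Path]:
    """Write stage-output tables as CSV plus a run manifest.

    Data files are byte-identical across runs with the same inputs; only
    the manifest carries a timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    manifest = {
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "tables": sorted(tables),
    }
    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths.append(manifest_path)
    return paths
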