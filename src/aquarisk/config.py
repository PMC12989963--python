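"""Study configuration.

The configuration collects the handful of scalar assumptions the risk
chain needs (adult body weight, the hazard-index threshold, assay
sensitivity, the study year window) plus the reserved label for
untraceable sources.  All of them are deliberately configuration rather
than constants: body weight and the year window vary between studies,
and assay sensitivity below 1 is a named sensitivity scenario.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import UNKNOWN, SchemaError


@dataclass(frozen=True)
class StudyConfig:
    """Scalar study assumptions.

    Parameters
    ----------
    body_weight
        Adult body weight in kg/person used in the daily-intake step.
    standard_value
        Hazard-index threshold above which a province is flagged
        (dimensionless; 1 by convention).
    detection_sensitivity
        Probability that the assay identifies a contaminated sample that
        was drawn, in (0, 1].  1.0 models perfect detection; 0.98 is the
        reported HPLC-GC sensitivity scenario.
    year_range
        Inclusive (start, end) years accepted for sampling records.
    seed
        Seed for every stochastic component (synthetic data, random
        instance generation).
    unknown_label
        Sentinel province code for untraceable sources.
    provinces
        Optional roster of valid province codes.  When ``None``, codes
        are accepted as opaque strings.
    """

    body_weight: float = 60.0
    standard_value: float = 1.0
    detection_sensitivity: float = 1.0
    year_range: tuple[int, int] = (2015, 2022)
    seed: int = 0
    unknown_label: str = UNKNOWN
    provinces: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise SchemaError("body_weight must be > 0")
        if self.standard_value <= 0:
            raise SchemaError("standard_value must be > 0")
        if not 0 < self.detection_sensitivity <= 1:
            raise SchemaError("detection_sensitivity must be in (0, 1]")
        lo, hi = self.year_range
        if lo > hi:
            raise SchemaError(f"year_range start {lo} exceeds end {hi}")

    def replace(self, **kwargs) -> "StudyConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["year_range"] = list(self.year_range)
        d["provinces"] = list(self.provinces) if self.provinces is not None else None
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise SchemaError(f"unknown config keys: {sorted(extra)}")
        data = dict(data)
        if "year_range" in data and data["year_range"] is not None:
            data["year_range"] = tuple(int(y) for y in data["year_range"])
        if data.get("provinces") is not None:
            data["provinces"] = tuple(str(p) for p in data["provinces"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
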