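"""Core domain types shared by every pipeline stage.

A *sampling record* is one tested product sample: where it was tested
(the monitoring province), where it came from (a source province, or the
``UNKNOWN`` sentinel when the origin is untraceable), the test outcome,
and — for failed samples — the list of hazard exceedances found.

Rates are stored as fractions in [0, 1] everywhere; percent formatting
happens only at report time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Reserved pseudo-province code for untraceable ("hidden middle") sources.
UNKNOWN = "UNKNOWN"

ANTIBIOTIC = "antibiotic"
OTHER = "other"
HAZARD_CLASSES = (ANTIBIOTIC, OTHER)

STREAM_INTERNAL = "internal"
STREAM_EXTERNAL = "external"
STREAM_UNKNOWN = "unknown"
STREAMS = (STREAM_INTERNAL, STREAM_EXTERNAL, STREAM_UNKNOWN)


class SchemaError(ValueError):
    """A tabular input violated the documented schema."""


@dataclass(frozen=True)
class Violation:
    """One hazard exceedance on a failed sample.

    ``limit`` is the legal ceiling in ug/kg; 0 encodes a zero-tolerance
    (prohibited) compound.  A violation row exists only for exceedances,
    so ``concentration`` must be strictly above ``limit``.
    """

    hazard_name: str
    hazard_class: str
    concentration: float
    limit: float

    def __post_init__(self) -> None:
        if self.hazard_class not in HAZARD_CLASSES:
            raise SchemaError(
                f"hazard_class must be one of {HAZARD_CLASSES}, got {self.hazard_class!r}"
            )
        if self.limit < 0:
            raise SchemaError(f"limit must be >= 0, got {self.limit}")
        if not self.concentration > self.limit:
            raise SchemaError(
                f"violation of {self.hazard_name!r} requires concentration > limit "
                f"({self.concentration} <= {self.limit})"
            )


@dataclass(frozen=True)
class SamplingRecord:
    """One tested sample, with its violations merged in."""

    sample_id: str
    year: int
    monitoring_province: str
    source_province: str
    product_category: str
    passed: bool
    violations: tuple[Violation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.violations) == 0):
            raise SchemaError(
                f"sample {self.sample_id!r}: passed={self.passed} but "
                f"{len(self.violations)} violation(s) attached"
            )
        if not self.monitoring_province:
            raise SchemaError(f"sample {self.sample_id!r}: monitoring province missing")


@dataclass(frozen=True)
class TradeRecord:
    """Province x year trade volumes in tons (production, export, import)."""

    province: str
    year: int
    production: float
    export: float
    import_: float

    def __post_init__(self) -> None:
        for name in ("production", "export", "import_"):
            if getattr(self, name) < 0:
                raise SchemaError(
                    f"{name} must be >= 0 for ({self.province}, {self.year})"
                )
        if self.production - self.export + self.import_ < 0:
            raise SchemaError(
                f"negative net trade volume for ({self.province}, {self.year}): "
                f"{self.production} - {self.export} + {self.import_} < 0"
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    """Daily per-capita aquatic intake, kg/person/day."""

    province: str
    year: int
    daily_intake: float

    def __post_init__(self) -> None:
        if not 0 < self.daily_intake < 5:
            # 5 kg/day flags obvious unit mistakes (g vs kg).
            raise SchemaError(
                f"daily_intake for ({self.province}, {self.year}) must be in (0, 5) "
                f"kg/person/day, got {self.daily_intake}"
            )


@dataclass(frozen=True)
class AntibioticReference:
    """ADI (ug/kg-bw/day) and MRL (ug/kg) for one antibiotic.

    ``adi`` may be ``None`` when no acceptable daily intake has been set;
    such compounds are excluded from hazard quotients with a warning.
    """

    antibiotic: str
    adi: float | None
    mrl: float

    def __post_init__(self) -> None:
        if self.adi is not None and self.adi <= 0:
            raise SchemaError(f"ADI for {self.antibiotic!r} must be > 0, got {self.adi}")
        if self.mrl < 0:
            raise SchemaError(f"MRL for {self.antibiotic!r} must be >= 0, got {self.mrl}")


def source_stream(source: str, monitor: str, unknown_label: str = UNKNOWN) -> str:
    """Classify a (source, monitor) flow as internal / external / unknown."""
    if source == unknown_label:
        return STREAM_UNKNOWN
    if source == monitor:
        return STREAM_INTERNAL
    return STREAM_EXTERNAL
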