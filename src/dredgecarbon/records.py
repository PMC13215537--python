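"""Harmonisation of heterogeneous extraction-event records into kilograms.

Extraction returns arrive in a mix of units — kilograms, imperial long tons
(1016 kg, the unit of 19th-century UK dredging returns), metric tonnes, cubic
metres, cubic yards — or carry only a monetary cost, or no quantity at all.
This module converts everything convertible to kg, annualises multi-year
period returns, applies the record-level exclusion rules (maerl, historical
non-aggregate categories) and the sparse-year rule (years covered by a single
country are dropped at shelf scale), and emits a canonical event table with a
provenance flag on every mass.

Coordinates, where present, are expected in a projected equal-area CRS in
metres (e.g. LAEA Europe, EPSG:3035); this module never reprojects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Industry", "QuantityUnit", "SedimentType", "MassProvenance",
    "ExtractionRecord", "HarmonisedEvent", "FilterAudit",
    "convert_quantity_to_mass", "exclude_record_categories",
    "exclude_sparse_years", "annualise_period_record", "harmonise_records",
    "read_records_csv", "write_events_csv",
    "LONG_TON_KG", "DEFAULT_DENSITY_KG_M3", "CUBIC_YARD_M3",
]

#: Imperial long ton, the "ton" of pre-1903 UK port returns.
LONG_TON_KG = 1016.0
#: Average wet bulk density of marine sediment used for volume -> mass.
DEFAULT_DENSITY_KG_M3 = 1700.0
#: One cubic yard in cubic metres (exact, from the international yard).
CUBIC_YARD_M3 = 0.764554857984


class Industry(str, Enum):
    PORT_DREDGING = "port_dredging"
    AGGREGATE = "aggregate"


class QuantityUnit(str, Enum):
    KG = "kg"
    TONNE_LONG_1016 = "tonne_long_1016"
    TONNE_METRIC = "tonne_metric"
    M3 = "m3"
    CUBIC_YARD = "cubic_yard"
    CURRENCY = "currency"
    ABSENT = "absent"


class SedimentType(str, Enum):
    SAND = "sand"
    COARSE = "coarse"
    MIXED = "mixed"
    UNKNOWN = "unknown"


class MassProvenance(str, Enum):
    REPORTED_MASS = "reported_mass"
    CONVERTED_VOLUME = "converted_volume"
    CONVERTED_COST = "converted_cost"
    IMPUTED = "imputed"


@dataclass(frozen=True)
class ExtractionRecord:
    """One dredging or aggregate-extraction event/return as reported.

    ``quantity_value`` is interpreted through ``quantity_unit``; ``absent``
    means the source evidences the works but gives no quantity or cost.
    ``site`` identifies the port or licence area (used for port-level
    aggregation of historical records); ``category`` carries the commodity
    tag used by the exclusion rules (e.g. ``"maerl"``).
    """

    record_id: str
    industry: Industry
    country: str
    year_start: int
    year_end: int
    quantity_value: float
    quantity_unit: QuantityUnit
    sediment_type: SedimentType = SedimentType.UNKNOWN
    site: str = ""
    category: str = ""
    location_wkt: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError(
                f"{self.record_id}: year_end {self.year_end} < year_start {self.year_start}"
            )
        if self.quantity_unit is not QuantityUnit.ABSENT and self.quantity_value < 0:
            raise ValueError(f"{self.record_id}: negative quantity_value")


@dataclass(frozen=True)
class HarmonisedEvent:
    """One canonical event in kilograms (or flagged for imputation).

    Annual events have ``year_end == year``.  A period record with no usable
    quantity is kept as a single period-level event with ``needs_imputation``
    set: the mass is drawn inside the Monte Carlo and annualised there, so the
    imputation happens once per dredging works, not once per calendar year.
    """

    record_id: str
    industry: Industry
    country: str
    year: int
    year_end: int
    mass_kg: float | None
    needs_imputation: bool
    sediment_type: SedimentType
    mass_provenance: MassProvenance | None
    site: str = ""

    def __post_init__(self) -> None:
        if self.needs_imputation == (self.mass_kg is not None):
            raise ValueError(f"{self.record_id}: exactly one of mass_kg / needs_imputation")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year + 1


@dataclass
class FilterAudit:
    """Dropped records with one reason code each (audit completeness)."""

    dropped: list = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    def add(self, record, reason: str) -> None:
        self.dropped.append(record)
        self.reasons.append(reason)

    def __len__(self) -> int:
        return len(self.dropped)

    def to_rows(self) -> list[dict]:
        return [
            {"record_id": r.record_id, "reason": why}
            for r, why in zip(self.dropped, self.reasons)
        ]


def convert_quantity_to_mass(
    value: float,
    unit: QuantityUnit | str,
    density_kg_m3: float = DEFAULT_DENSITY_KG_M3,
) -> float:
    """Convert a reported quantity to kilograms.

    kg pass through; long tons multiply by 1016, metric tonnes by 1000;
    volumes multiply by the sediment density (default 1700 kg/m3), cubic
    yards via 0.764554858 m3/yd3 first.  Monetary and absent quantities are
    rejected here — they are handled by the imputation module.
    """
    unit = QuantityUnit(unit)
    if value < 0:
        raise ValueError("quantity must be non-negative")
    if density_kg_m3 <= 0:
        raise ValueError("density must be positive")
    if unit is QuantityUnit.KG:
        return float(value)
    if unit is QuantityUnit.TONNE_LONG_1016:
        return value * LONG_TON_KG
    if unit is QuantityUnit.TONNE_METRIC:
        return value * 1000.0
    if unit is QuantityUnit.M3:
        return value * density_kg_m3
    if unit is QuantityUnit.CUBIC_YARD:
        return value * CUBIC_YARD_M3 * density_kg_m3
    raise ValueError(f"unit {unit.value!r} is not a mass or volume unit")


#: Historical commodity/category tags excluded from the aggregate analysis:
#: maerl (no TOC characterisation) and pre-1980 non-aggregate extraction.
DEFAULT_EXCLUDED_CATEGORIES = frozenset(
    {"maerl", "tin_prospecting", "clay", "shingle", "borehole"}
)


def exclude_record_categories(
    records: Sequence[ExtractionRecord],
    excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
) -> tuple[list[ExtractionRecord], FilterAudit]:
    """Drop records whose ``category`` tag is on the exclusion list.

    Returns (retained, audit); every input record lands in exactly one.
    """
    excluded = {c.lower() for c in excluded_categories}
    retained: list[ExtractionRecord] = []
    audit = FilterAudit()
    for rec in records:
        cat = rec.category.lower()
        if cat and cat in excluded:
            audit.add(rec, cat)
        else:
            retained.append(rec)
    return retained, audit


def exclude_sparse_years(
    events: Sequence[HarmonisedEvent],
    min_countries: int = 2,
) -> tuple[list[HarmonisedEvent], FilterAudit]:
    """Drop shelf-scale years covered by too few countries.

    Years in which only a single nation reported would be large shelf-scale
    underestimates, so for each (industry, year) with fewer than
    ``min_countries`` distinct contributing countries all events are dropped.
    A period event counts toward (and is judged on) every year in its span;
    it is dropped only if all of its years are sparse.
    """
    contributors: dict[tuple[Industry, int], set[str]] = {}
    for ev in events:
        for yr in range(ev.year, ev.year_end + 1):
            contributors.setdefault((ev.industry, yr), set()).add(ev.country)
    sparse = {key for key, ctys in contributors.items() if len(ctys) < min_countries}
    retained: list[HarmonisedEvent] = []
    audit = FilterAudit()
    for ev in events:
        span = [(ev.industry, yr) for yr in range(ev.year, ev.year_end + 1)]
        if all(key in sparse for key in span):
            audit.add(ev, f"sparse_years:{ev.year}-{ev.year_end}")
        else:
            retained.append(ev)
    return retained, audit


def annualise_period_record(
    record: ExtractionRecord,
    density_kg_m3: float = DEFAULT_DENSITY_KG_M3,
) -> list[HarmonisedEvent]:
    """Split one record into annual events; mass conserved exactly.

    A convertible quantity is divided equally (as real numbers, no rounding)
    across the years of the period; the per-year masses sum to the input mass
    to within floating tolerance.  A record with no quantity (absent or
    cost-only at this stage) yields ONE period-level ``needs_imputation``
    event spanning the full period.
    """
    common = dict(
        record_id=record.record_id,
        industry=record.industry,
        country=record.country,
        sediment_type=record.sediment_type,
        site=record.site,
    )
    if record.quantity_unit in (QuantityUnit.ABSENT, QuantityUnit.CURRENCY):
        return [
            HarmonisedEvent(
                year=record.year_start,
                year_end=record.year_end,
                mass_kg=None,
                needs_imputation=True,
                mass_provenance=None,
                **common,
            )
        ]
    total = convert_quantity_to_mass(record.quantity_value, record.quantity_unit, density_kg_m3)
    prov = (
        MassProvenance.REPORTED_MASS
        if record.quantity_unit in (QuantityUnit.KG, QuantityUnit.TONNE_LONG_1016, QuantityUnit.TONNE_METRIC)
        else MassProvenance.CONVERTED_VOLUME
    )
    years = range(record.year_start, record.year_end + 1)
    per_year = total / len(years)
    return [
        HarmonisedEvent(
            year=yr,
            year_end=yr,
            mass_kg=per_year,
            needs_imputation=False,
            mass_provenance=prov,
            **common,
        )
        for yr in years
    ]


def harmonise_records(
    records: Sequence[ExtractionRecord],
    cost_model=None,
    density_kg_m3: float = DEFAULT_DENSITY_KG_M3,
) -> list[HarmonisedEvent]:
    """Full harmonisation: cost conversion where possible, then annualisation.

    Records priced in currency are converted to mass through ``cost_model``
    (see :func:`dredgecarbon.imputation.fit_cost_rate`) when one is supplied;
    otherwise they fall through to ``needs_imputation``.  Idempotent in the
    sense that re-annualising the emitted annual events changes nothing.
    """
    events: list[HarmonisedEvent] = []
    for rec in records:
        if rec.quantity_unit is QuantityUnit.CURRENCY and cost_model is not None:
            from .imputation import estimate_mass_from_cost

            total = estimate_mass_from_cost(rec.quantity_value, cost_model)
            years = range(rec.year_start, rec.year_end + 1)
            per_year = total / len(years)
            events.extend(
                HarmonisedEvent(
                    record_id=rec.record_id,
                    industry=rec.industry,
                    country=rec.country,
                    year=yr,
                    year_end=yr,
                    mass_kg=per_year,
                    needs_imputation=False,
                    sediment_type=rec.sediment_type,
                    mass_provenance=MassProvenance.CONVERTED_COST,
                    site=rec.site,
                )
                for yr in years
            )
        else:
            events.extend(annualise_period_record(rec, density_kg_m3))
    return events


# ---------------------------------------------------------------------------
# CSV interface


_RECORD_COLUMNS = [
    "record_id", "industry", "country", "year_start", "year_end",
    "quantity_value", "quantity_unit", "sediment_type", "site", "category",
    "location_wkt", "source_tag",
]


def read_records_csv(path) -> list[ExtractionRecord]:
    """Read an extraction-record table (UTF-8 CSV, header row)."""
    records: list[ExtractionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                records.append(
                    ExtractionRecord(
                        record_id=row["record_id"],
                        industry=Industry(row["industry"]),
                        country=row["country"],
                        year_start=int(row["year_start"]),
                        year_end=int(row["year_end"]),
                        quantity_value=float(row["quantity_value"] or 0.0),
                        quantity_unit=QuantityUnit(row["quantity_unit"]),
                        sediment_type=SedimentType(row.get("sediment_type") or "unknown"),
                        site=row.get("site", ""),
                        category=row.get("category", ""),
                        location_wkt=row.get("location_wkt", ""),
                        source_tag=row.get("source_tag", ""),
                    )
                )
            except (KeyError, ValueError) as err:
                raise ValueError(f"{path}: row {i + 2}: {err}") from err
    return records


def write_records_csv(records: Sequence[ExtractionRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_RECORD_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(
                {
                    "record_id": rec.record_id,
                    "industry": rec.industry.value,
                    "country": rec.country,
                    "year_start": rec.year_start,
                    "year_end": rec.year_end,
                    "quantity_value": repr(rec.quantity_value),
                    "quantity_unit": rec.quantity_unit.value,
                    "sediment_type": rec.sediment_type.value,
                    "site": rec.site,
                    "category": rec.category,
                    "location_wkt": rec.location_wkt,
                    "source_tag": rec.source_tag,
                }
            )


def write_events_csv(events: Sequence[HarmonisedEvent], path) -> None:
    """Write harmonised events; empty mass column marks needs_imputation."""
    cols = [
        "record_id", "industry", "country", "year", "year_end", "mass_kg",
        "needs_imputation", "sediment_type", "mass_provenance", "site",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for ev in events:
            writer.writerow(
                {
                    "record_id": ev.record_id,
                    "industry": ev.industry.value,
                    "country": ev.country,
                    "year": ev.year,
                    "year_end": ev.year_end,
                    "mass_kg": "" if ev.mass_kg is None else repr(ev.mass_kg),
                    "needs_imputation": int(ev.needs_imputation),
                    "sediment_type": ev.sediment_type.value,
                    "mass_provenance": ev.mass_provenance.value if ev.mass_provenance else "",
                    "site": ev.site,
                }
            )


def read_events_csv(path) -> list[HarmonisedEvent]:
    events: list[HarmonisedEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            needs = bool(int(row["needs_imputation"]))
            events.append(
                HarmonisedEvent(
                    record_id=row["record_id"],
                    industry=Industry(row["industry"]),
                    country=row["country"],
                    year=int(row["year"]),
                    year_end=int(row["year_end"]),
                    mass_kg=None if needs else float(row["mass_kg"]),
                    needs_imputation=needs,
                    sediment_type=SedimentType(row["sediment_type"]),
                    mass_provenance=(
                        MassProvenance(row["mass_provenance"]) if row["mass_provenance"] else None
                    ),
                    site=row.get("site", ""),
                )
            )
    return events
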