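"""Domain types and file plumbing: censored measurements, sources, mines.

CSV is the interchange format (UTF-8, header row); a column-mapping *dialect*
decouples the canonical field names from whatever a given survey file calls
them.  Map export is RFC 7946 GeoJSON with [lon, lat] point coordinates.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)


class Analyte(str, enum.Enum):
    ARSENIC = "arsenic"
    URANIUM = "uranium"


class Units(str, enum.Enum):
    UG_PER_L = "ug_per_L"
    PCI_PER_L = "pCi_per_L"


@dataclass(frozen=True)
class CensoredMeasurement:
    """One analytical result: a detected value or a nondetect below a limit.

    ``value`` is present iff the analyte was detected; a censored result
    carries only its reporting limit (the laboratory LOD).  Activity units
    (pCi/L) are permitted for uranium only.
    """

    analyte: Analyte
    censored: bool
    value: float | None = None
    reporting_limit: float | None = None
    units: Units = Units.UG_PER_L
    survey_id: str = ""
    sample_date: str | None = None
    method_documented: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "units", Units(self.units))
        if self.censored:
            if self.value is not None:
                raise ValueError("censored measurement must not carry a value")
            if self.reporting_limit is None or not self.reporting_limit > 0:
                raise ValueError("censored measurement requires reporting_limit > 0")
        else:
            if self.value is None or self.value < 0:
                raise ValueError("detected measurement requires value >= 0")
        if self.units is Units.PCI_PER_L and self.analyte is not Analyte.URANIUM:
            raise ValueError("pCi/L units are permitted only for uranium")

    @property
    def magnitude(self) -> float:
        """Detected value, or the reporting limit for a nondetect."""
        return self.reporting_limit if self.censored else self.value  # type: ignore[return-value]


@dataclass
class SourceRecord:
    """An unregulated water source and its per-analyte measurement history."""

    source_id: str
    lat: float
    lon: float
    region: str = ""
    source_type: str | None = None
    measurements: list[CensoredMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.source_type not in (None, "well", "spring", "storage_tank"):
            raise ValueError(f"unknown source_type {self.source_type!r}")

    def measurements_for(self, analyte: Analyte | str) -> list[CensoredMeasurement]:
        analyte = Analyte(analyte)
        return [m for m in self.measurements if m.analyte is analyte]


@dataclass(frozen=True)
class MineSite:
    """An abandoned uranium mine location (WGS84 decimal degrees)."""

    mine_id: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


# ---------------------------------------------------------------------------
# CSV dialects

#: canonical column names for the long-format source/measurement table
SOURCE_COLUMNS = (
    "source_id", "lat", "lon", "region", "source_type", "analyte",
    "value", "censored", "reporting_limit", "units", "survey_id",
    "sample_date", "method_documented",
)
_REQUIRED_SOURCE_COLUMNS = ("source_id", "lat", "lon", "analyte", "censored")
MINE_COLUMNS = ("mine_id", "lat", "lon")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class CsvDialect:
    """Mapping from canonical column names to the columns of a survey file.

    Only names that differ need to be listed; canonical optional columns
    absent from the file are filled with defaults.
    """

    columns: Mapping[str, str] = field(default_factory=dict)

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class RowRejection:
    """Diagnostic for one input row that failed validation."""

    row: int          # 0-based data-row index (header excluded)
    source_id: str
    reason: str


@dataclass
class ReadResult:
    sources: list[SourceRecord]
    rejections: list[RowRejection]

    @property
    def n_measurements(self) -> int:
        return sum(len(s.measurements) for s in self.sources)


def _parse_bool(raw, *, default: bool | None = None) -> bool:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        if default is None:
            raise ValueError("missing boolean")
        return default
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        if s == "":
            if default is None:
                raise ValueError("missing boolean")
            return default
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def _opt_float(raw) -> float | None:
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        return None
    v = float(raw)
    return None if math.isnan(v) else v


def read_sources(path: str | Path, dialect: CsvDialect | None = None) -> ReadResult:
    """Read a long-format measurement CSV and group rows into SourceRecords.

    One output record per distinct ``source_id``; invalid rows (unparseable
    coordinates, censored without a reporting limit, ...) are collected as
    :class:`RowRejection` diagnostics rather than raising.  A missing
    *required* column is a configuration error and raises ``ValueError``.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SOURCE_COLUMNS if dialect.resolve(c) not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing} in {path}")
    if df.empty:
        log.warning("no data rows in %s", path)
        return ReadResult([], [])

    def col(name, row):
        c = dialect.resolve(name)
        return row[c] if c in df.columns else None

    by_source: dict[str, SourceRecord] = {}
    rejections: list[RowRejection] = []
    for i, row in enumerate(df.to_dict("records")):
        sid = str(col("source_id", row) or "").strip()
        try:
            if not sid:
                raise ValueError("empty source_id")
            lat = float(col("lat", row))
            lon = float(col("lon", row))
            meas = CensoredMeasurement(
                analyte=Analyte(str(col("analyte", row)).strip().lower()),
                censored=_parse_bool(col("censored", row)),
                value=_opt_float(col("value", row)),
                reporting_limit=_opt_float(col("reporting_limit", row)),
                units=Units(str(col("units", row) or "ug_per_L").strip() or "ug_per_L"),
                survey_id=str(col("survey_id", row) or "").strip(),
                sample_date=(str(col("sample_date", row)).strip() or None)
                if col("sample_date", row) is not None else None,
                method_documented=_parse_bool(col("method_documented", row), default=True),
            )
            rec = by_source.get(sid)
            if rec is None:
                rec = SourceRecord(
                    source_id=sid, lat=lat, lon=lon,
                    region=str(col("region", row) or "").strip(),
                    source_type=(str(col("source_type", row)).strip() or None)
                    if col("source_type", row) is not None else None,
                )
                by_source[sid] = rec
            rec.measurements.append(meas)
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(row=i, source_id=sid, reason=str(exc)))
    if rejections:
        log.warning("rejected %d of %d rows", len(rejections), len(df))
    return ReadResult(list(by_source.values()), rejections)


def write_sources(sources: Iterable[SourceRecord], path: str | Path,
                  dialect: CsvDialect | None = None) -> None:
    """Write SourceRecords back to the long-format CSV (read_sources inverse)."""
    dialect = dialect or CsvDialect()
    rows = []
    for s in sources:
        for m in s.measurements:
            rows.append({
                dialect.resolve("source_id"): s.source_id,
                dialect.resolve("lat"): repr(s.lat),
                dialect.resolve("lon"): repr(s.lon),
                dialect.resolve("region"): s.region,
                dialect.resolve("source_type"): s.source_type or "",
                dialect.resolve("analyte"): m.analyte.value,
                dialect.resolve("value"): "" if m.value is None else repr(m.value),
                dialect.resolve("censored"): str(m.censored).lower(),
                dialect.resolve("reporting_limit"):
                    "" if m.reporting_limit is None else repr(m.reporting_limit),
                dialect.resolve("units"): m.units.value,
                dialect.resolve("survey_id"): m.survey_id,
                dialect.resolve("sample_date"): m.sample_date or "",
                dialect.resolve("method_documented"): str(m.method_documented).lower(),
            })
    cols = [dialect.resolve(c) for c in SOURCE_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_mines(path: str | Path, dialect: CsvDialect | None = None) -> list[MineSite]:
    """Read an abandoned-mine location table (mine_id, lat, lon)."""
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MINE_COLUMNS if dialect.resolve(c) not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing} in {path}")
    return [
        MineSite(
            mine_id=str(row[dialect.resolve("mine_id")]),
            lat=float(row[dialect.resolve("lat")]),
            lon=float(row[dialect.resolve("lon")]),
        )
        for row in df.to_dict("records")
    ]


def write_mines(mines: Iterable[MineSite], path: str | Path) -> None:
    pd.DataFrame(
        [{"mine_id": m.mine_id, "lat": repr(m.lat), "lon": repr(m.lon)} for m in mines],
        columns=list(MINE_COLUMNS),
    ).to_csv(path, index=False)


def write_geojson(sources: Sequence[SourceRecord],
                  summaries: Mapping[str, Mapping[str, object]],
                  path: str | Path) -> None:
    """Export sources as a GeoJSON FeatureCollection of Points.

    ``summaries`` maps source_id to a flat property dict (per-analyte
    concentration, censored flags, MCL exceedance booleans); properties are
    passed through verbatim.  Coordinates follow the [lon, lat] axis order of
    RFC 7946.
    """
    features = []
    for s in sources:
        props: dict[str, object] = {"source_id": s.source_id, "region": s.region}
        if s.source_type:
            props["source_type"] = s.source_type
        props.update(summaries.get(s.source_id, {}))
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
            "properties": props,
        })
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=2, sort_keys=True) + "\n")
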