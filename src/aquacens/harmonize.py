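"""Data-selection rules: unit conversion, documentation screen, max-per-source.

Multi-survey compilations mix mass (ug/L) and activity (pCi/L) uranium
results and repeat visits to the same source.  Harmonization puts every
result on the ug/L scale, drops results whose laboratory method or censoring
level is undocumented, and collapses each source+analyte history to its
maximum observation — an exposure-screening convention that keeps any source
capable of exceeding a drinking-water standard visible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .config import AnalysisConfig
from .data_model import Analyte, CensoredMeasurement, SourceRecord, Units


@dataclass(frozen=True)
class HarmonizedValue:
    """Per-source analysis value for one analyte, on the ug/L scale.

    ``value_ug_L`` is the detected concentration, or the reporting limit if
    the retained observation is censored.
    """

    source_id: str
    analyte: Analyte
    value_ug_L: float
    censored: bool
    n_samples_collapsed: int = 1
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.value_ug_L > 0:
            raise ValueError("value_ug_L must be strictly positive")
        if self.n_samples_collapsed < 1:
            raise ValueError("n_samples_collapsed must be >= 1")


@dataclass
class ExclusionRecord:
    source_id: str
    reason: str            # "undocumented" | "censored_without_limit"
    n_dropped: int


def activity_to_mass(activity: float, pci_per_ug: float = 0.67) -> float:
    """Convert a uranium activity concentration (pCi/L) to mass (ug/L).

    The same linear factor applies to detected values and reporting limits:
    a censored activity bound becomes a censored mass bound.
    """
    if activity < 0:
        raise ValueError("activity must be non-negative")
    if not pci_per_ug > 0:
        raise ValueError("pci_per_ug must be strictly positive")
    return activity / pci_per_ug


def to_mass_units(m: CensoredMeasurement, pci_per_ug: float = 0.67) -> CensoredMeasurement:
    """Return the measurement expressed in ug/L (identity if already mass)."""
    if m.units is Units.UG_PER_L:
        return m
    return replace(
        m,
        units=Units.UG_PER_L,
        value=None if m.value is None else activity_to_mass(m.value, pci_per_ug),
        reporting_limit=None if m.reporting_limit is None
        else activity_to_mass(m.reporting_limit, pci_per_ug),
    )


def apply_inclusion_rules(
    records: Iterable[SourceRecord],
) -> tuple[list[SourceRecord], list[ExclusionRecord]]:
    """Drop measurements without documented method/censoring level.

    Filtering is per measurement; a source whose measurements are all removed
    moves to the exclusion report with a reason code.  Sources are never
    mutated: retained sources with dropped measurements are shallow-copied.
    """
    included: list[SourceRecord] = []
    excluded: list[ExclusionRecord] = []
    for rec in records:
        kept, reasons = [], []
        for m in rec.measurements:
            if not m.method_documented:
                reasons.append("undocumented")
            elif m.censored and (m.reporting_limit is None or not m.reporting_limit > 0):
                reasons.append("censored_without_limit")
            else:
                kept.append(m)
        if kept:
            if len(kept) < len(rec.measurements):
                rec = SourceRecord(rec.source_id, rec.lat, rec.lon, rec.region,
                                   rec.source_type, kept)
            included.append(rec)
        else:
            excluded.append(ExclusionRecord(
                source_id=rec.source_id,
                reason=reasons[0] if reasons else "no_measurements",
                n_dropped=len(rec.measurements),
            ))
    return included, excluded


def max_per_source(measurements: Sequence[CensoredMeasurement]) -> HarmonizedValue:
    """Collapse one source+analyte history to its maximum observation.

    Magnitude is the detected value, or the reporting limit for a nondetect
    (a high-limit nondetect stays visible for exposure screening).  When a
    detected value ties a censored limit, the detected one wins: it carries
    more information.  All inputs must already be in ug/L.
    """
    if not measurements:
        raise ValueError("max_per_source requires at least one measurement")
    analytes = {m.analyte for m in measurements}
    if len(analytes) != 1:
        raise ValueError("measurements must share one analyte")
    if any(m.units is not Units.UG_PER_L for m in measurements):
        raise ValueError("convert to ug/L before aggregation")
    # sort key: magnitude first, detected beats censored on ties
    best = max(measurements, key=lambda m: (m.magnitude, not m.censored))
    return HarmonizedValue(
        source_id="",
        analyte=best.analyte,
        value_ug_L=best.magnitude,
        censored=best.censored,
        n_samples_collapsed=len(measurements),
        provenance=tuple(dict.fromkeys(m.survey_id for m in measurements if m.survey_id)),
    )


def harmonize_records(
    records: Iterable[SourceRecord],
    config: AnalysisConfig | None = None,
) -> tuple[dict[Analyte, list[HarmonizedValue]], list[ExclusionRecord]]:
    """Full selection chain: convert units, screen documentation, take maxima.

    Returns one :class:`HarmonizedValue` per source per analyte present,
    keyed by analyte, plus the exclusion report.
    """
    config = config or AnalysisConfig()
    included, excluded = apply_inclusion_rules(records)
    out: dict[Analyte, list[HarmonizedValue]] = {a: [] for a in Analyte}
    for rec in included:
        for analyte in Analyte:
            ms = [to_mass_units(m, config.pci_per_ug)
                  for m in rec.measurements_for(analyte)]
            if not ms:
                continue
            hv = max_per_source(ms)
            out[analyte].append(replace_source_id(hv, rec.source_id))
    return out, excluded


def replace_source_id(hv: HarmonizedValue, source_id: str) -> HarmonizedValue:
    return HarmonizedValue(source_id, hv.analyte, hv.value_ug_L, hv.censored,
                           hv.n_samples_collapsed, hv.provenance)
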