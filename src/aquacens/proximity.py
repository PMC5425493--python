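"""Distance to the nearest abandoned mine, near/far partition, profiles.

Distances are great-circle (haversine) kilometres on a sphere of mean radius
6371.0088 km; at the 6.4 km partition granularity the spherical-vs-ellipsoidal
error is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .censored_stats import (
    ExceedanceSummary,
    TwoGroupTest,
    paired_values,
    peto_peto_test,
    summarize_analyte,
    summarize_joint,
)
from .data_model import Analyte, MineSite, SourceRecord
from .harmonize import HarmonizedValue
from .ros import UnsupportedDataError, ros_fit

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between WGS84 points (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class ProximityResult:
    """Nearest-mine assignment for one source."""

    source_id: str
    nearest_mine_id: str
    distance_km: float
    near: bool

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ValueError("distance_km must be non-negative")


def nearest_mines(sources: Sequence[SourceRecord], mines: Sequence[MineSite],
                  config: AnalysisConfig | None = None) -> list[ProximityResult]:
    """Nearest mine per source; ties go to the first mine in input order."""
    config = config or AnalysisConfig()
    if not mines:
        raise ValueError("at least one mine location is required")
    m_lat = np.array([m.lat for m in mines])
    m_lon = np.array([m.lon for m in mines])
    out = []
    for s in sources:
        d = haversine_km(s.lat, s.lon, m_lat, m_lon)
        j = int(np.argmin(d))       # argmin returns the first minimum
        out.append(ProximityResult(
            source_id=s.source_id,
            nearest_mine_id=mines[j].mine_id,
            distance_km=float(d[j]),
            near=bool(d[j] < config.distance_threshold_km),
        ))
    return out


def nearest_mine(source: SourceRecord, mines: Sequence[MineSite],
                 config: AnalysisConfig | None = None) -> ProximityResult:
    return nearest_mines([source], mines, config)[0]


def partition_summaries(
    by_analyte: dict[Analyte, list[HarmonizedValue]],
    proximity: Sequence[ProximityResult],
    config: AnalysisConfig | None = None,
    warnings: list[str] | None = None,
) -> tuple[list[ExceedanceSummary], dict[Analyte, TwoGroupTest | None]]:
    """Near/far stratum rows plus a censored two-group test per analyte.

    Every source referenced by a value must have a proximity result.  A
    stratum too sparse for the ROS fit gets a row with the affected
    statistics marked unavailable; a stratum too sparse for the two-group
    test yields ``None`` with a warning.
    """
    config = config or AnalysisConfig()
    warnings = warnings if warnings is not None else []
    near_ids = {p.source_id for p in proximity if p.near}
    all_ids = {p.source_id for p in proximity}
    rows: list[ExceedanceSummary] = []
    tests: dict[Analyte, TwoGroupTest | None] = {}
    t = config.distance_threshold_km
    strata = ((f"<{t:g} km from mine", True), (f">{t:g} km from mine", False))

    for analyte in Analyte:
        values = by_analyte.get(analyte, [])
        missing = {v.source_id for v in values} - all_ids
        if missing:
            raise ValueError(f"no proximity result for source(s): {sorted(missing)[:5]}")
        groups = {True: [], False: []}
        for v in values:
            groups[v.source_id in near_ids].append(v)
        for label, is_near in strata:
            if groups[is_near]:
                rows.append(summarize_analyte(label, analyte, groups[is_near],
                                              config, warnings))
            else:
                warnings.append(f"{label}/{analyte.value}: empty stratum")
        try:
            tests[analyte] = peto_peto_test(groups[False], groups[True])
        except UnsupportedDataError as exc:
            warnings.append(f"near/far test skipped for {analyte.value}: {exc}")
            tests[analyte] = None

    pairs = paired_values(by_analyte)
    for label, is_near in strata:
        sel = [p for p in pairs if (p[0].source_id in near_ids) == is_near]
        if sel:
            rows.append(summarize_joint(label, sel, config, warnings))
    return rows, tests


@dataclass(frozen=True)
class DistanceProfile:
    """Per-distance-bin ROS medians with the overall median as reference."""

    analyte: Analyte
    bin_edges: np.ndarray          # (n_bins + 1,) km, contiguous from 0
    n: np.ndarray                  # (n_bins,) sources per bin
    median_ug_L: np.ndarray        # (n_bins,) per-bin median (NaN if empty)
    overall_median_ug_L: float
    fallback: np.ndarray           # (n_bins,) True where limit/sqrt(2) substitution
    low_n: np.ndarray              # (n_bins,) True where n < 3

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def _substitution_median(values: Sequence[HarmonizedValue]) -> float:
    # fallback for bins too sparse for ROS: nondetects at limit/sqrt(2)
    x = np.array([v.value_ug_L / math.sqrt(2.0) if v.censored else v.value_ug_L
                  for v in values])
    return float(np.median(x))


def distance_profile(values: Sequence[HarmonizedValue],
                     proximity: Sequence[ProximityResult],
                     bin_km: float | None = None,
                     config: AnalysisConfig | None = None) -> DistanceProfile:
    """Median concentration as a function of distance from the nearest mine.

    Sources fall in contiguous bins [i*bin, (i+1)*bin); each bin reports the
    ROS median, with a flagged limit/sqrt(2) substitution median where the
    bin cannot support the ROS fit, and NaN for empty bins.
    """
    config = config or AnalysisConfig()
    bin_km = float(bin_km if bin_km is not None else config.profile_bin_km)
    if not bin_km > 0:
        raise ValueError("bin_km must be strictly positive")
    if not values:
        raise UnsupportedDataError("no values to profile")
    dist = {p.source_id: p.distance_km for p in proximity}
    missing = [v.source_id for v in values if v.source_id not in dist]
    if missing:
        raise ValueError(f"no proximity result for source(s): {missing[:5]}")
    analyte = values[0].analyte
    d = np.array([dist[v.source_id] for v in values])
    n_bins = max(1, int(np.floor(d.max() / bin_km)) + 1)
    edges = np.arange(n_bins + 1) * bin_km
    idx = np.minimum((d / bin_km).astype(int), n_bins - 1)

    n = np.zeros(n_bins, dtype=int)
    med = np.full(n_bins, np.nan)
    fallback = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        sel = [v for v, i in zip(values, idx) if i == b]
        n[b] = len(sel)
        if not sel:
            continue
        try:
            med[b] = ros_fit(sel).summary_["median"]
        except UnsupportedDataError:
            med[b] = _substitution_median(sel)
            fallback[b] = True
    try:
        overall = ros_fit(values).summary_["median"]
    except UnsupportedDataError:
        overall = _substitution_median(values)
    return DistanceProfile(
        analyte=analyte, bin_edges=edges, n=n, median_ug_L=med,
        overall_median_ug_L=float(overall),
        fallback=fallback, low_n=n < 3,
    )
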