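"""Pipeline orchestration and report emission.

``run_pipeline`` chains the full analysis — read, harmonize, summarize
overall and per region, partition by mine proximity, profile by distance,
export the map layer — and writes a bundle of CSV/GeoJSON outputs plus a
JSON manifest listing configuration, input/output digests, stage timings
and accumulated warnings.

Report tables carry each fraction twice: the full-precision fraction and a
percentage rounded to one decimal place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .censored_stats import (
    ExceedanceSummary,
    classify_exceedance,
    paired_values,
    summarize_analyte,
    summarize_joint,
)
from .data_model import Analyte, CsvDialect, MineSite, SourceRecord, read_mines, \
    read_sources, write_geojson
from .harmonize import HarmonizedValue, harmonize_records
from .proximity import distance_profile, nearest_mines, partition_summaries
from .ros import UnsupportedDataError, ros_fit

log = logging.getLogger(__name__)

OVERALL = "overall"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def significance_flag(p: float | None, alpha_levels: Sequence[float]) -> str:
    """One star per alpha level the p-value falls below (smallest alphas last)."""
    if p is None or not np.isfinite(p):
        return ""
    return "*" * sum(p < a for a in alpha_levels)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    inputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    outputs: dict[str, dict] = field(default_factory=dict)  # name -> {path, sha256}
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings_s": self.timings_s,
            "warnings": self.warnings,
            "seed": self.seed,
            "counts": self.counts,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _summary_row(s: ExceedanceSummary, alpha_levels: Sequence[float]) -> dict:
    def pct(f):
        return None if f is None else round(100.0 * f, 1)

    return {
        "block": s.block,
        "stratum": s.stratum,
        "n": s.n,
        "detection_frequency": s.detection_frequency,
        "detection_frequency_pct": pct(s.detection_frequency),
        "ros_median_ug_L": s.ros_median,
        "ros_p25_ug_L": None if s.ros_iqr is None else s.ros_iqr[0],
        "ros_p75_ug_L": None if s.ros_iqr is None else s.ros_iqr[1],
        "frac_exceed_mcl": s.frac_exceed_mcl,
        "pct_exceed_mcl": pct(s.frac_exceed_mcl),
        "n_indeterminate": s.n_indeterminate,
        "frac_exceed_half_both": s.frac_exceed_half_both,
        "pct_exceed_half_both": pct(s.frac_exceed_half_both),
        "frac_exceed_both": s.frac_exceed_both,
        "pct_exceed_both": pct(s.frac_exceed_both),
        "tau": s.tau,
        "tau_p": s.tau_p,
        "tau_flag": significance_flag(s.tau_p, alpha_levels) if s.tau is not None else "",
    }


def summary_tables(by_analyte: Mapping[Analyte, list[HarmonizedValue]],
                   regions: Mapping[str, str],
                   config: AnalysisConfig,
                   warnings: list[str]) -> pd.DataFrame:
    """Overall + per-region rows in three blocks (As, U, As-and-U)."""
    region_order = sorted(set(regions.values()))
    rows: list[dict] = []

    def strata(values):
        yield OVERALL, values
        for r in region_order:
            yield r, [v for v in values if regions.get(v.source_id) == r]

    for analyte in Analyte:
        for label, vals in strata(by_analyte.get(analyte, [])):
            if not vals:
                warnings.append(f"{label}/{analyte.value}: empty stratum")
                continue
            rows.append(_summary_row(
                summarize_analyte(label, analyte, vals, config, warnings),
                config.alpha_levels))
    pairs = paired_values(dict(by_analyte))
    for label, _ in strata([]):
        sel = (pairs if label == OVERALL
               else [p for p in pairs if regions.get(p[0].source_id) == label])
        if not sel:
            warnings.append(f"{label}/arsenic_uranium: no pairs")
            continue
        rows.append(_summary_row(
            summarize_joint(label, sel, config, warnings), config.alpha_levels))
    return pd.DataFrame(rows)


def _geojson_summaries(by_analyte: Mapping[Analyte, list[HarmonizedValue]],
                       config: AnalysisConfig,
                       warnings: list[str]) -> dict[str, dict]:
    """Per-source map properties: imputed-or-observed value + exceedance flags."""
    props: dict[str, dict] = {}
    for analyte in Analyte:
        values = by_analyte.get(analyte, [])
        if not values:
            continue
        tag = "as" if analyte is Analyte.ARSENIC else "u"
        imputed = {}
        try:
            fit = ros_fit(values)
            imputed = {v.source_id: float(c)
                       for v, c in zip(values, fit.combined_values_) if v.censored}
        except UnsupportedDataError as exc:
            warnings.append(f"geojson/{analyte.value}: imputation unavailable ({exc})")
        mcl = config.mcl(analyte.value)
        for v in values:
            p = props.setdefault(v.source_id, {})
            p[f"{tag}_ug_L"] = imputed.get(v.source_id, v.value_ug_L)
            p[f"{tag}_censored"] = v.censored
            p[f"exceeds_{tag}"] = classify_exceedance(v, mcl).exceeds
    return props


def run_pipeline(sources_csv: str | Path,
                 mines_csv: str | Path | None,
                 out_dir: str | Path,
                 config: AnalysisConfig | None = None,
                 dialect: CsvDialect | None = None,
                 seed: int | None = None) -> RunManifest:
    """Run the full analysis and write the report bundle into ``out_dir``.

    With ``mines_csv=None`` the proximity partition, two-group tests and
    distance profile are skipped.  Stratum-level failures (too few detects
    for a ROS fit, ...) are recorded as warnings and the run continues.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=seed)
    warnings = manifest.warnings
    t0 = time.perf_counter()

    result = read_sources(sources_csv, dialect)
    sources = result.sources
    for r in result.rejections:
        warnings.append(f"rejected row {r.row} ({r.source_id!r}): {r.reason}")
    manifest.inputs[str(sources_csv)] = _sha256(Path(sources_csv))
    mines: list[MineSite] = []
    if mines_csv is not None:
        mines = read_mines(mines_csv)
        manifest.inputs[str(mines_csv)] = _sha256(Path(mines_csv))
    manifest.timings_s["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    by_analyte, excluded = harmonize_records(sources, config)
    for e in excluded:
        warnings.append(f"excluded source {e.source_id}: {e.reason}")
    included_ids = {v.source_id for vs in by_analyte.values() for v in vs}
    kept_sources = [s for s in sources if s.source_id in included_ids]
    regions = {s.source_id: s.region for s in kept_sources}
    manifest.counts = {
        "sources_read": len(sources),
        "sources_analyzed": len(kept_sources),
        "sources_excluded": len(excluded),
        "rows_rejected": len(result.rejections),
        "mines": len(mines),
    }
    manifest.timings_s["harmonize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summary = summary_tables(by_analyte, regions, config, warnings)
    _write_csv(summary, out / "summary.csv", manifest, "summary")
    manifest.timings_s["summary"] = time.perf_counter() - t0

    if mines:
        t0 = time.perf_counter()
        prox = nearest_mines(kept_sources, mines, config)
        rows, tests = partition_summaries(by_analyte, prox, config, warnings)
        prox_df = pd.DataFrame([_summary_row(r, config.alpha_levels) for r in rows])
        _write_csv(prox_df, out / "proximity.csv", manifest, "proximity")
        tests_df = pd.DataFrame([
            {
                "analyte": a.value,
                "chi_square": None if t is None else t.statistic,
                "p_value": None if t is None else t.p_value,
                "flag": "" if t is None else significance_flag(
                    t.p_value, config.alpha_levels),
                "n_far": None if t is None else t.group_sizes[0],
                "n_near": None if t is None else t.group_sizes[1],
            }
            for a, t in tests.items()
        ])
        _write_csv(tests_df, out / "proximity_tests.csv", manifest, "proximity_tests")

        profiles = []
        for analyte in Analyte:
            values = by_analyte.get(analyte, [])
            if not values:
                continue
            prof = distance_profile(values, prox, config.profile_bin_km, config)
            for b in range(len(prof.n)):
                profiles.append({
                    "analyte": analyte.value,
                    "bin_lo_km": prof.bin_edges[b],
                    "bin_hi_km": prof.bin_edges[b + 1],
                    "n": prof.n[b],
                    "median_ug_L": prof.median_ug_L[b],
                    "overall_median_ug_L": prof.overall_median_ug_L,
                    "fallback": bool(prof.fallback[b]),
                    "low_n": bool(prof.low_n[b]),
                })
                if prof.fallback[b]:
                    warnings.append(
                        f"profile/{analyte.value} bin {b}: substitution fallback")
        _write_csv(pd.DataFrame(profiles), out / "profile.csv", manifest, "profile")
        manifest.timings_s["proximity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    geo_path = out / "sources.geojson"
    write_geojson(kept_sources, _geojson_summaries(by_analyte, config, warnings),
                  geo_path)
    manifest.outputs["geojson"] = {"path": str(geo_path), "sha256": _sha256(geo_path)}
    manifest.timings_s["geojson"] = time.perf_counter() - t0

    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = {"path": str(out / "manifest.json")}
    for w in warnings:
        log.warning("%s", w)
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest, name: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.outputs[name] = {"path": str(path), "sha256": _sha256(path)}
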