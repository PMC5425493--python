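"""Analysis configuration: regulatory thresholds, unit conversion, distances."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and constants driving the exceedance and proximity analysis.

    Parameters
    ----------
    mcl_arsenic : float
        Arsenic maximum contaminant level, ug/L (US SDWA value: 10).
    mcl_uranium : float
        Uranium maximum contaminant level, ug/L (US SDWA value: 30).
    half_mcl_fraction : float
        Fraction of the MCL used for the co-exceedance screen (default 0.5).
    pci_per_ug : float
        Assumed uranium activity-to-mass equivalence, pCi per ug (default 0.67).
    distance_threshold_km : float
        Near/far partition distance to the nearest abandoned mine, km
        (default 6.4 km = 4 miles).
    profile_bin_km : float
        Bin width for the distance-concentration profile, km.
    alpha_levels : tuple of float
        Significance levels used to annotate p-values in reports.
    """

    mcl_arsenic: float = 10.0
    mcl_uranium: float = 30.0
    half_mcl_fraction: float = 0.5
    pci_per_ug: float = 0.67
    distance_threshold_km: float = 6.4
    profile_bin_km: float = 5.0
    alpha_levels: tuple[float, ...] = (0.01, 0.001)

    def __post_init__(self) -> None:
        for name in ("mcl_arsenic", "mcl_uranium", "pci_per_ug",
                     "distance_threshold_km", "profile_bin_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.half_mcl_fraction < 1.0:
            raise ValueError("half_mcl_fraction must lie in (0, 1)")
        if any(not 0.0 < a < 1.0 for a in self.alpha_levels):
            raise ValueError("alpha levels must lie in (0, 1)")

    def mcl(self, analyte: str) -> float:
        """MCL in ug/L for an analyte name ('arsenic' or 'uranium')."""
        try:
            return {"arsenic": self.mcl_arsenic, "uranium": self.mcl_uranium}[analyte]
        except KeyError:
            raise ValueError(f"unknown analyte: {analyte!r}") from None

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a flat ``key = value`` file ('#' starts a comment).

        ``alpha_levels`` is a comma-separated list; unknown keys raise.
        """
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key == "alpha_levels":
                kwargs[key] = tuple(float(v) for v in val.split(","))
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "mcl_arsenic": self.mcl_arsenic,
            "mcl_uranium": self.mcl_uranium,
            "half_mcl_fraction": self.half_mcl_fraction,
            "pci_per_ug": self.pci_per_ug,
            "distance_threshold_km": self.distance_threshold_km,
            "profile_bin_km": self.profile_bin_km,
            "alpha_levels": list(self.alpha_levels),
        }
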