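"""Exceedance classification, As-U correlation, and censored two-group test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .data_model import Analyte
from .harmonize import HarmonizedValue
from .ros import UnsupportedDataError, _as_arrays


class ExceedanceFlag(NamedTuple):
    """Threshold classification of one analysis value.

    ``exceeds`` is true only for a *detected* value above the threshold.  A
    nondetect never counts as an exceedance, but one whose reporting limit is
    itself above the threshold cannot be ruled out and carries the
    ``indeterminate`` diagnostic flag.
    """

    exceeds: bool
    indeterminate: bool


def classify_exceedance(value: HarmonizedValue, threshold: float) -> ExceedanceFlag:
    if not threshold > 0:
        raise ValueError("threshold must be strictly positive")
    if value.censored:
        return ExceedanceFlag(False, value.value_ug_L > threshold)
    return ExceedanceFlag(value.value_ug_L > threshold, False)


class CoExceedance(NamedTuple):
    exceeds_both: bool
    exceeds_half_both: bool
    detected_both: bool


def co_exceedance(as_val: HarmonizedValue, u_val: HarmonizedValue,
                  config: AnalysisConfig | None = None) -> CoExceedance:
    """Joint As/U classification for one source at full and half MCLs."""
    config = config or AnalysisConfig()
    if as_val.analyte is not Analyte.ARSENIC or u_val.analyte is not Analyte.URANIUM:
        raise ValueError("expected (arsenic, uranium) value pair")
    both = (classify_exceedance(as_val, config.mcl_arsenic).exceeds
            and classify_exceedance(u_val, config.mcl_uranium).exceeds)
    f = config.half_mcl_fraction
    half = (classify_exceedance(as_val, f * config.mcl_arsenic).exceeds
            and classify_exceedance(u_val, f * config.mcl_uranium).exceeds)
    return CoExceedance(both, half, not as_val.censored and not u_val.censored)


def kendall_tau(pairs: Sequence[tuple[HarmonizedValue, HarmonizedValue]] | None = None,
                x=None, y=None, *, min_pairs: int = 10) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b between paired As/U analysis values.

    Nondetects enter at their reporting limit, so two nondetects at the same
    limit are indistinguishable and count as a tie; the p-value uses the
    normal approximation with tie-corrected variance.  Accepts either a list
    of (as, u) HarmonizedValue pairs or two numeric vectors ``x``/``y``.
    """
    if pairs is not None:
        x = np.asarray([a.value_ug_L for a, _ in pairs], dtype=float)
        y = np.asarray([u.value_ug_L for _, u in pairs], dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < min_pairs:
        raise UnsupportedDataError(
            f"need at least {min_pairs} pairs for the correlation, got {x.size}")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ExceedanceSummary:
    """One summary-table row for a stratum (region, near/far group, overall).

    Single-analyte rows fill ``ros_median``/``ros_iqr``/``frac_exceed_mcl``;
    joint As-U rows fill the correlation and co-exceedance fields instead.
    Statistics are ``None`` when the stratum cannot support them (too few
    detects for the ROS fit, too few pairs for the correlation).
    """

    stratum: str
    block: str                      # "arsenic" | "uranium" | "arsenic_uranium"
    n: int
    detection_frequency: float
    ros_median: float | None = None
    ros_iqr: tuple[float, float] | None = None
    frac_exceed_mcl: float | None = None
    n_indeterminate: int = 0
    frac_exceed_half_both: float | None = None
    frac_exceed_both: float | None = None
    tau: float | None = None
    tau_p: float | None = None

    def __post_init__(self) -> None:
        fracs = [f for f in (self.detection_frequency, self.frac_exceed_mcl,
                             self.frac_exceed_half_both, self.frac_exceed_both)
                 if f is not None]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if (self.frac_exceed_both is not None
                and self.frac_exceed_half_both is not None
                and self.frac_exceed_both > self.frac_exceed_half_both + 1e-12):
            raise ValueError("frac_exceed_both cannot exceed frac_exceed_half_both")


def summarize_analyte(stratum: str, analyte: Analyte | str,
                      values: Sequence[HarmonizedValue],
                      config: AnalysisConfig | None = None,
                      warnings: list[str] | None = None) -> ExceedanceSummary:
    """Detection/median/MCL-exceedance row for one analyte in one stratum."""
    from .ros import ros_fit  # local import to keep module load order simple

    config = config or AnalysisConfig()
    analyte = Analyte(analyte)
    if not values:
        raise UnsupportedDataError(f"stratum {stratum!r}: no values")
    mcl = config.mcl(analyte.value)
    flags = [classify_exceedance(v, mcl) for v in values]
    median = iqr = None
    try:
        fit = ros_fit(values)
        median = fit.summary_["median"]
        iqr = (fit.summary_["p25"], fit.summary_["p75"])
    except UnsupportedDataError as exc:
        if warnings is not None:
            warnings.append(f"{stratum}/{analyte.value}: ROS unavailable ({exc})")
    return ExceedanceSummary(
        stratum=stratum,
        block=analyte.value,
        n=len(values),
        detection_frequency=float(np.mean([not v.censored for v in values])),
        ros_median=median,
        ros_iqr=iqr,
        frac_exceed_mcl=float(np.mean([f.exceeds for f in flags])),
        n_indeterminate=int(sum(f.indeterminate for f in flags)),
    )


def summarize_joint(stratum: str,
                    pairs: Sequence[tuple[HarmonizedValue, HarmonizedValue]],
                    config: AnalysisConfig | None = None,
                    warnings: list[str] | None = None) -> ExceedanceSummary:
    """Co-detection, correlation and co-exceedance row for paired As/U values."""
    config = config or AnalysisConfig()
    if not pairs:
        raise UnsupportedDataError(f"stratum {stratum!r}: no As/U pairs")
    co = [co_exceedance(a, u, config) for a, u in pairs]
    tau = tau_p = None
    try:
        tau, tau_p = kendall_tau(pairs)
    except UnsupportedDataError as exc:
        if warnings is not None:
            warnings.append(f"{stratum}/arsenic_uranium: tau unavailable ({exc})")
    return ExceedanceSummary(
        stratum=stratum,
        block="arsenic_uranium",
        n=len(pairs),
        detection_frequency=float(np.mean([c.detected_both for c in co])),
        frac_exceed_half_both=float(np.mean([c.exceeds_half_both for c in co])),
        frac_exceed_both=float(np.mean([c.exceeds_both for c in co])),
        tau=tau,
        tau_p=tau_p,
    )


def paired_values(by_analyte: dict[Analyte, list[HarmonizedValue]],
                  ) -> list[tuple[HarmonizedValue, HarmonizedValue]]:
    """Match per-source As and U values; sources missing one analyte are skipped."""
    u_by_id = {v.source_id: v for v in by_analyte.get(Analyte.URANIUM, [])}
    return [(a, u_by_id[a.source_id])
            for a in by_analyte.get(Analyte.ARSENIC, [])
            if a.source_id in u_by_id]


@dataclass(frozen=True)
class TwoGroupTest:
    """Censored two-group comparison reported as a 1-df chi-square."""

    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    score: float      # signed score U; positive when group_b sits higher

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be non-negative")


def peto_peto_test(group_a, group_b, censored_a=None, censored_b=None,
                   flip_constant: float | None = None) -> TwoGroupTest:
    """Peto-Peto generalized Wilcoxon test for two left-censored samples.

    The data are flipped to right-censored form (subtracted from a constant
    above every value and limit), and the log-rank-family score statistic
    with rho = 1 weights — the Kaplan-Meier survival estimate just before
    each event time — is computed with the hypergeometric variance.  The
    squared normalized score is reported as a chi-square with 1 df.  The
    result is invariant to the choice of flip constant, which only shifts
    the event times.

    Each group needs >= 5 observations and >= 1 detect; groups in which every
    observation is an identical nondetect carry no ranking information.
    """
    mags_a, cens_a = _as_arrays(group_a, censored_a)
    mags_b, cens_b = _as_arrays(group_b, censored_b)
    for name, mags, cens in (("group_a", mags_a, cens_a), ("group_b", mags_b, cens_b)):
        if mags.size < 5:
            raise UnsupportedDataError(f"{name} needs >= 5 observations, got {mags.size}")
        if cens.all():
            raise UnsupportedDataError(f"{name} needs at least one detected value")

    mags = np.concatenate([mags_a, mags_b])
    cens = np.concatenate([cens_a, cens_b])
    in_b = np.concatenate([np.zeros(mags_a.size, bool), np.ones(mags_b.size, bool)])

    flip = mags.max() + 1.0 if flip_constant is None else float(flip_constant)
    if flip <= mags.max():
        raise ValueError("flip_constant must exceed every value and limit")
    time = flip - mags
    event = ~cens          # a detect is an observed event after flipping

    U = 0.0
    V = 0.0
    S = 1.0                # left-continuous KM on the combined sample
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int((event & (time == t)).sum())
        n_b = int((at_risk & in_b).sum())
        d_b = int((event & (time == t) & in_b).sum())
        w = S
        U += w * (d_b - d * n_b / n)
        if n > 1:
            V += w * w * d * (n - d) * n_b * (n - n_b) / (n * n * (n - 1))
        S *= 1.0 - d / n
    if V <= 0:
        raise UnsupportedDataError("degenerate groups: zero score variance")
    # after flipping, more early events in b means b has *higher* concentrations
    chi2 = U * U / V
    return TwoGroupTest(
        statistic=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        group_sizes=(int(mags_a.size), int(mags_b.size)),
        score=float(U),
    )
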