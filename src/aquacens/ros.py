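"""Robust regression on order statistics (ROS) for multiply left-censored data.

The estimator assigns each observation a plotting position via the
exceedance-probability recursion for multiple censoring levels
(Hirsch-Stedinger), regresses the natural log of the *detected* values on
the normal scores of their positions, imputes each nondetect from the fitted
line at its own position, and computes summary statistics on the combined
set of observed and imputed values in the original units.  Because imputed
values are retransformed individually, no lognormal back-transform bias
correction is applied — the "robust" variant.

Notation, for distinct censoring limits L_1 < ... < L_k and a virtual limit
L_0 below all data:

* ``A_j`` — detected values in the closed-left interval [L_j, L_{j+1});
* ``B_j`` — observations known to lie below L_j (detects < L_j plus
  nondetects with limit <= L_j);
* ``C_j`` — nondetects censored exactly at L_j;
* ``P_j`` — probability of exceeding L_j, computed top-down:
  ``P_j = P_{j+1} + A_j/(A_j+B_j) * (1 - P_{j+1})`` with ``P_{k+1} = 0``
  and ``P_0 = 1`` (everything exceeds the virtual limit).

Detected values in interval j, ranked i = 1..A_j, take the position
``(1-P_j) + (P_j-P_{j+1}) * i/(A_j+1)``; nondetects at L_j take
``(1-P_j) * i/(C_j+1)``.  With no censoring this is exactly the Weibull
position i/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator


class UnsupportedDataError(ValueError):
    """Raised when data violate a stated precondition (too few detects, ...)."""


def _as_arrays(values, censored=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (magnitudes, censored flags) or a sequence of HarmonizedValue."""
    if censored is None:
        mags = np.asarray([v.value_ug_L for v in values], dtype=float)
        cens = np.asarray([v.censored for v in values], dtype=bool)
    else:
        mags = np.asarray(values, dtype=float)
        cens = np.asarray(censored, dtype=bool)
        if mags.shape != cens.shape:
            raise ValueError("values and censored must have the same length")
    return mags, cens


@dataclass(frozen=True)
class CensoringCensus:
    """Interval census of a multiply-censored sample.

    Arrays are indexed j = 0..k where index 0 is the virtual limit below all
    data and ``limits`` holds the k distinct censoring levels ascending.
    """

    limits: np.ndarray       # (k,) distinct censoring limits, ascending
    detects_in_interval: np.ndarray   # A_j, shape (k+1,)
    below_limit: np.ndarray           # B_j, shape (k+1,), B_0 = 0
    censored_at_limit: np.ndarray     # C_j, shape (k+1,), C_0 = 0
    n_total: int

    @property
    def n_levels(self) -> int:
        return len(self.limits)


def censoring_census(values, censored=None) -> CensoringCensus:
    """Tabulate A_j / B_j / C_j counts for each censoring level.

    A detected value exactly equal to a limit belongs to the interval at and
    above that limit (closed-left convention).
    """
    mags, cens = _as_arrays(values, censored)
    if mags.size == 0:
        raise UnsupportedDataError("need at least one observation")
    det = mags[~cens]
    lim = mags[cens]
    limits = np.unique(lim)
    k = len(limits)
    A = np.zeros(k + 1, dtype=int)
    B = np.zeros(k + 1, dtype=int)
    C = np.zeros(k + 1, dtype=int)
    # interval index of each detect: number of limits <= value (closed-left)
    idx = np.searchsorted(limits, det, side="right")
    np.add.at(A, idx, 1)
    for j in range(1, k + 1):
        L = limits[j - 1]
        B[j] = int((det < L).sum() + (lim <= L).sum())
        C[j] = int((lim == L).sum())
    return CensoringCensus(limits=limits, detects_in_interval=A, below_limit=B,
                           censored_at_limit=C, n_total=int(mags.size))


def exceedance_probabilities(census: CensoringCensus) -> np.ndarray:
    """Exceedance probability P_j at each limit, top-down recursion.

    Returns an array of length k+2: ``P[0] = 1`` at the virtual limit,
    ``P[1..k]`` at the censoring limits, ``P[k+1] = 0``.  Levels with
    ``A_j + B_j = 0`` inherit the level above.
    """
    k = census.n_levels
    P = np.zeros(k + 2)
    for j in range(k, 0, -1):
        denom = census.detects_in_interval[j] + census.below_limit[j]
        if denom == 0:
            P[j] = P[j + 1]
        else:
            P[j] = P[j + 1] + census.detects_in_interval[j] / denom * (1.0 - P[j + 1])
    P[0] = 1.0
    return P


def plotting_positions(values, censored=None, *, census: CensoringCensus | None = None,
                       probs: np.ndarray | None = None) -> np.ndarray:
    """Plotting position in (0, 1) for every observation, in input order."""
    mags, cens = _as_arrays(values, censored)
    if census is None:
        census = censoring_census(mags, cens)
    if probs is None:
        probs = exceedance_probabilities(census)
    limits = census.limits
    A, C = census.detects_in_interval, census.censored_at_limit
    p = np.empty(mags.shape)

    det_pos = np.flatnonzero(~cens)
    interval = np.searchsorted(limits, mags[det_pos], side="right")
    order = np.lexsort((det_pos, mags[det_pos]))  # ascending value, stable
    rank_in_interval = np.zeros(len(det_pos), dtype=int)
    seen: dict[int, int] = {}
    for o in order:
        j = int(interval[o])
        seen[j] = seen.get(j, 0) + 1
        rank_in_interval[o] = seen[j]
    for o, j in enumerate(interval):
        i = rank_in_interval[o]
        p[det_pos[o]] = (1.0 - probs[j]) + (probs[j] - probs[j + 1]) * i / (A[j] + 1)

    cen_pos = np.flatnonzero(cens)
    level = np.searchsorted(limits, mags[cen_pos]) + 1  # exact-match index + 1
    seen = {}
    for o, j in enumerate(level):
        j = int(j)
        seen[j] = seen.get(j, 0) + 1
        p[cen_pos[o]] = (1.0 - probs[j]) * seen[j] / (C[j] + 1)
    return p


def detection_frequency(values, censored=None) -> float:
    """Fraction of observations that are detected (uncensored)."""
    mags, cens = _as_arrays(values, censored)
    if mags.size == 0:
        raise UnsupportedDataError("need at least one observation")
    return float((~cens).mean())


class RobustROS(BaseEstimator):
    """Robust ROS summary-statistics estimator for left-censored samples.

    Fit on magnitudes (detected value, or reporting limit for nondetects)
    plus a censoring indicator; the fitted object exposes the plotting
    positions, the log-scale regression line, per-nondetect imputed values,
    and summary statistics of the combined observed+imputed sample.

    Parameters
    ----------
    percentiles : tuple of float
        Percentiles (0-100) reported in ``summary_`` in addition to the
        mean/sd/median/IQR block.  Linear interpolation between order
        statistics (Hyndman-Fan type 7).

    Attributes
    ----------
    slope_, intercept_ : float
        Coefficients of the least-squares fit of ln(detected value) on the
        normal score of its plotting position; estimate log-sd and log-mean.
    imputed_values_ : ndarray
        Model value ``exp(intercept + slope * z)`` for each nondetect, in
        input order.  For summaries only — never reported as measurements.
    combined_values_ : ndarray, length n
        Observed detects and imputed nondetects, in input order.
    summary_ : dict
        mean, sd (ddof=1), median, p25, p75, iqr and requested percentiles,
        all in original units.

    Notes
    -----
    Requires >= 3 detected values with >= 2 distinct magnitudes and strictly
    positive data (the log transform); otherwise :class:`UnsupportedDataError`
    is raised rather than silently substituting.
    """

    def __init__(self, percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)):
        self.percentiles = percentiles

    def fit(self, values, censored=None) -> "RobustROS":
        mags, cens = _as_arrays(values, censored)
        if mags.size == 0:
            raise UnsupportedDataError("need at least one observation")
        if np.any(mags <= 0):
            raise UnsupportedDataError(
                "all values and reporting limits must be strictly positive "
                "(log transform)")
        detects = mags[~cens]
        if detects.size < 3:
            raise UnsupportedDataError(
                f"need at least 3 detected values to fit the regression, "
                f"got {detects.size}")
        if np.unique(detects).size < 2:
            raise UnsupportedDataError(
                "need at least 2 distinct detected magnitudes")

        census = censoring_census(mags, cens)
        probs = exceedance_probabilities(census)
        pos = plotting_positions(mags, cens, census=census, probs=probs)
        z = stats.norm.ppf(pos)

        zd, yd = z[~cens], np.log(detects)
        slope, intercept = np.polyfit(zd, yd, 1)

        imputed = np.exp(intercept + slope * z[cens])
        combined = mags.copy()
        combined[cens] = imputed

        self.n_total_ = int(mags.size)
        self.n_censored_ = int(cens.sum())
        self.censoring_levels_ = census.limits.copy()
        self.census_ = census
        self.exceedance_probs_ = probs
        self.plotting_positions_ = pos
        self.normal_scores_ = z
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.imputed_values_ = imputed
        self.combined_values_ = combined
        self.detection_frequency_ = float((~cens).mean())
        q = {f"p{g:g}": float(np.percentile(combined, g)) for g in self.percentiles}
        self.summary_ = {
            "mean": float(np.mean(combined)),
            "sd": float(np.std(combined, ddof=1)) if mags.size > 1 else 0.0,
            "median": float(np.percentile(combined, 50.0)),
            "p25": float(np.percentile(combined, 25.0)),
            "p75": float(np.percentile(combined, 75.0)),
            **q,
        }
        self.summary_["iqr"] = self.summary_["p75"] - self.summary_["p25"]
        return self

    def to_dict(self) -> dict:
        """JSON-serializable view of the fit."""
        return {
            "n_total": self.n_total_,
            "n_censored": self.n_censored_,
            "censoring_levels": self.censoring_levels_.tolist(),
            "exceedance_probs": self.exceedance_probs_.tolist(),
            "slope": self.slope_,
            "intercept": self.intercept_,
            "detection_frequency": self.detection_frequency_,
            "summary": self.summary_,
        }


def ros_fit(values, censored=None, **params) -> RobustROS:
    """Fit a :class:`RobustROS` model; thin functional wrapper."""
    return RobustROS(**params).fit(values, censored)
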