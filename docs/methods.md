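# Methods

## Problem setting

The package analyzes per-sample water-quality records for two analytes
(arsenic and uranium) measured in unregulated drinking-water sources by
multiple surveys. Each record is either a detected concentration or a
nondetect below a survey- and analyte-specific reporting limit. Because
surveys used different laboratories and methods, a pooled dataset is
*multiply* left-censored: several distinct limits, some above other surveys'
detected values, and uranium reported in either mass (µg/L) or activity
(pCi/L) units. The quantities of interest are summary statistics (median,
IQR, mean), the frequency of maximum-contaminant-level (MCL) exceedance and
As–U co-exceedance, the As–U rank correlation, and whether concentrations
differ by proximity to abandoned uranium mines.

## Harmonization rules

1. **Unit conversion.** Uranium activity is converted to mass as
   `µg/L = pCi/L ÷ pci_per_ug` with `pci_per_ug = 0.67` by default, applied
   identically to detected values and reporting limits (a censored activity
   bound is a censored mass bound). The conversion is linear and invertible;
   mixed-unit source histories are compared on the mass scale only.
2. **Documentation screen.** Measurements lacking a documented laboratory
   method, or censored without a stated limit, are dropped per measurement;
   a source with nothing left moves to an exclusion report with a reason
   code.
3. **Maximum per source.** A source's history for one analyte collapses to
   the observation with the largest magnitude, where a nondetect ranks by
   its reporting limit. This is an exposure-screening convention: it keeps
   every source that could exceed a standard visible, at the cost of an
   upward bias for repeatedly sampled sources. A detected value beats a
   censored bound of equal magnitude because it carries more information.

## Robust ROS

For distinct censoring limits `L_1 < … < L_k` plus a virtual limit `L_0`
below all data, the sample is censused into `A_j` (detects in
`[L_j, L_{j+1})`, closed on the left), `B_j` (observations known below
`L_j`: detects `< L_j` plus nondetects with limit `≤ L_j`) and `C_j`
(nondetects at `L_j`). Exceedance probabilities follow the top-down
recursion `P_j = P_{j+1} + A_j/(A_j+B_j) · (1 − P_{j+1})`, `P_{k+1} = 0`;
the virtual level has `P_0 = 1` exactly (every observation exceeds it),
which the recursion itself yields whenever any detect falls below `L_1`.
Levels where `A_j + B_j = 0` inherit the value above. These probabilities
coincide with a Kaplan–Meier survival estimator computed on the flipped
(right-censored) sample; the test suite checks that identity exhaustively on
small instances.

Plotting positions interpolate within each interval: detects ranked
`i = 1..A_j` get `(1−P_j) + (P_j−P_{j+1}) · i/(A_j+1)`; nondetects at `L_j`
get `(1−P_j) · i/(C_j+1)`. Without censoring this is exactly the Weibull
position `i/(n+1)`. The natural log of the detected values is regressed
(ordinary least squares) on the normal scores `Φ⁻¹(p)`; the slope and
intercept estimate the log-scale SD and mean. Each nondetect is imputed as
`exp(intercept + slope·Φ⁻¹(p))` at its own position, and summary statistics
are computed on the combined detected + imputed sample in original units.
Imputing individual values and retransforming them — rather than
retransforming moments — avoids the lognormal back-transform bias, so no
Cohn-type correction is applied. Imputed values feed summaries only and are
never exported as measurements.

Numerical conventions:

- **Closed-left intervals**: a detect exactly equal to a limit counts in the
  interval at/above that limit.
- **Log base**: natural; retransformed summaries are base-invariant.
- **Percentiles**: linear interpolation between order statistics
  (Hyndman–Fan type 7, the numpy default) — IQR values depend on this.
- **Preconditions**: at least 3 detects with 2 distinct magnitudes and
  strictly positive data; violations raise an explicit error rather than
  silently substituting. Tied observations are exchangeable: their
  positions are assigned by input order within the tie group, so
  per-observation positions are permutation-invariant as a multiset.
- With zero nondetects the summary equals the ordinary sample statistics
  exactly.

## Exceedance and correlation

A nondetect never counts as an exceedance; when its reporting limit lies
above the threshold the classification is flagged *indeterminate* in
diagnostics rather than guessed. Co-exceedance uses the same rule at the
full MCLs and at `half_mcl_fraction × MCL` (default 0.5). Consequently
exceedance frequencies are lower bounds in strata containing high-limit
nondetects; the indeterminate count is reported alongside.

Kendall's tau is the tie-corrected tau-b on per-source analysis values with
nondetects entered at their reporting limits, so indistinguishable censored
bounds tie; the p-value uses the tie-corrected normal approximation. Limit
substitution biases tau toward zero when limits are informative; a fully
censored-data tau is out of scope by design.

## Two-group comparison

Near/far concentration differences are tested with the Peto–Peto
generalized Wilcoxon test: values and limits are flipped to right-censored
survival times by subtracting from a constant above the sample maximum
(the statistic is invariant to the constant), and the log-rank-family score
with ρ = 1 weights — the left-continuous Kaplan–Meier estimate of the
combined sample — is computed with the hypergeometric variance and reported
as a 1-df chi-square. This weighting matches the generalized-Wilcoxon
variant used by the standard survival tooling for censored environmental
data. With no censoring the subject scores are affine in rank, so the
statistic is permutation-equivalent to the Wilcoxon rank-sum test. Each
group needs ≥ 5 observations and ≥ 1 detect.

## Proximity and profiles

Distances are haversine great-circle kilometres (sphere radius
6371.0088 km); the spherical approximation errs by far less than the 6.4 km
partition granularity. "Near" means strictly less than the threshold.
The distance profile bins sources at a configurable width (default 5 km)
and reports the per-bin ROS median against the overall ROS median; bins too
sparse for the ROS fit fall back to a flagged limit/√2 substitution median,
and bins with n < 3 are flagged low-n. Bin medians are an explicit design
choice for the profile; no smoothing is applied.

## Synthetic generator

The generator emulates the structure the analysis assumes, with known
ground truth:

- **Layout**: mines and sources uniform in a bounding box spanning roughly
  3° × 4.4° (~130,000 km²); region labels are contiguous longitude strips.
  The geometry is deliberately abstract — it reproduces a realistic
  near/far split (~40 % of sources within 6.4 km of a mine) but no real
  geography.
- **Marginals**: lognormal As and U with default medians 2.0 and 3.8 µg/L
  and log-SD 1.4, typical of trace-element groundwater surveys.
- **Dependence**: a Gaussian copula. Because the mine enrichment multiplies
  both analytes' medians and itself induces rank correlation, the copula
  correlation is solved net of the realized shared log-variance so the
  *total* latent Kendall tau hits the target (default 0.23); with the
  enrichment off this reduces to `ρ = sin(πτ/2)`.
- **Mine effect**: the true median is multiplied by
  `1 + (E₀−1)·exp(−d/s)` with `E₀ = 8` and `s = 5 km`, returning to
  background by ~30 km. Under the uniform-mine layout almost no source is
  more than ~25 km from a mine, so the observable near/far median ratio is
  ~2 — weaker than a clustered-mine landscape would show — and the default
  `E₀` is set so the planted ordering is reliably detectable at the default
  sample size, which is the construction guarantee the tests rely on.
- **Surveys**: seven survey definitions with reporting limits spanning
  0.01–10 µg/L, three reporting uranium in pCi/L (limits stated in pCi/L
  and values stored in activity units); each sample is assigned a survey
  with probability proportional to the survey's historical sample count.
  Censoring is a deterministic function of the latent value versus the
  survey's limit on the mass scale.
- **Repeat sampling**: 20 % of sources get a second visit with lognormal
  revisit noise (log-SD 0.3, a loose calibration to the per-source
  variability such compilations report); the harmonizer's max rule then
  collapses them.

What the generator does *not* emulate: spatial autocorrelation of the
baseline (beyond the mine effect), clustered mine districts, geochemical
covariates, non-lognormal tails, seasonal structure, or informative
censoring. Passing tests therefore demonstrate the statistical machinery is
correct under its stated assumptions, not that those assumptions hold for
any particular aquifer.

## Problem sizes and defaults

The default study shape is 468 sources and 521 mines. Calibration suites
use 200 replicates of n = 500 (with n ∈ {100, 2000} for consistency
checks) for ROS mean recovery, 1000 null replicates of 50 + 50 for the
two-group test's size, 100 seeds for planted-effect power, and n = 2000 for
copula calibration — sizes at which the Monte-Carlo error of each check is
comfortably below the tolerance it asserts.

## Limitations

- The max-per-source rule makes stratum summaries screening statistics, not
  unbiased concentration estimates.
- Exceedance frequencies treat high-limit nondetects as non-exceedances
  (flagged), so they are lower bounds.
- Tau under limit substitution is attenuated when censoring is heavy.
- The choice of the ρ = 1 score test for the near/far comparison is one of
  several defensible censored two-sample tests; its chi-square values are
  not comparable across weighting conventions.
- ROS confidence intervals are not provided; only point summaries.
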