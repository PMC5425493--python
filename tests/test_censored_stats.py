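import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquacens import (
    AnalysisConfig,
    Analyte,
    UnsupportedDataError,
    classify_exceedance,
    co_exceedance,
    kendall_tau,
    peto_peto_test,
)
from aquacens.censored_stats import ExceedanceSummary, summarize_analyte, summarize_joint

from conftest import hv, hvs


class TestClassifyExceedance:
    # truth table over the four (censored, magnitude-vs-threshold) cases
    @pytest.mark.parametrize("value,censored,threshold,exceeds,indet", [
        (12.0, False, 10.0, True, False),   # detected above the As MCL
        (8.0, False, 10.0, False, False),
        (5.0, True, 10.0, False, False),    # bound below threshold
        (15.0, True, 10.0, False, True),    # limit above threshold: unknowable
    ])
    def test_truth_table(self, value, censored, threshold, exceeds, indet):
        flag = classify_exceedance(hv(value, censored), threshold)
        assert (flag.exceeds, flag.indeterminate) == (exceeds, indet)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_exceedance(hv(1.0), 0.0)


class TestCoExceedance:
    def test_half_mcl_but_not_full(self, config):
        out = co_exceedance(hv(6.0), hv(16.0, analyte=Analyte.URANIUM), config)
        assert out.exceeds_half_both and not out.exceeds_both
        assert out.detected_both

    def test_both_full_mcls(self, config):
        out = co_exceedance(hv(12.0), hv(31.0, analyte=Analyte.URANIUM), config)
        assert out.exceeds_both and out.exceeds_half_both

    def test_nondetect_never_exceeds(self, config):
        out = co_exceedance(hv(1.0, censored=True),
                            hv(40.0, analyte=Analyte.URANIUM), config)
        assert not out.exceeds_both and not out.exceeds_half_both
        assert not out.detected_both

    def test_analyte_order_enforced(self, config):
        with pytest.raises(ValueError):
            co_exceedance(hv(1.0, analyte=Analyte.URANIUM), hv(1.0), config)

    @given(st.lists(st.tuples(st.floats(0.1, 50), st.floats(0.1, 80),
                              st.booleans(), st.booleans()),
                    min_size=1, max_size=30),
           st.floats(5, 20), st.floats(15, 60))
    @settings(deadline=None, max_examples=50)
    def test_raising_mcls_never_increases_counts(self, rows, mcl_as, mcl_u):
        base = AnalysisConfig()
        raised = AnalysisConfig(mcl_arsenic=base.mcl_arsenic + mcl_as,
                                mcl_uranium=base.mcl_uranium + mcl_u)
        pairs = [(hv(a, ca), hv(u, cu, analyte=Analyte.URANIUM))
                 for a, u, ca, cu in rows]
        for field in ("exceeds_both", "exceeds_half_both"):
            n_base = sum(getattr(co_exceedance(a, u, base), field)
                         for a, u in pairs)
            n_raised = sum(getattr(co_exceedance(a, u, raised), field)
                           for a, u in pairs)
            assert n_raised <= n_base


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    n = len(x)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        conc += s > 0
        disc += s < 0
    tx = sum(t * (t - 1) / 2 for t in np.unique(x, return_counts=True)[1])
    ty = sum(t * (t - 1) / 2 for t in np.unique(y, return_counts=True)[1])
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_perfect_concordance(self):
        x = np.arange(1.0, 11.0)
        tau, p = kendall_tau(x=x, y=2 * x)
        assert tau == pytest.approx(1.0)
        assert p < 0.001

    def test_ties_match_brute_force_oracle(self):
        x = np.array([1, 2, 2, 3, 4, 5, 5, 6, 7, 8, 9, 9], float)
        y = np.array([2, 1, 4, 3, 3, 7, 5, 8, 6, 9, 9, 10], float)
        tau, _ = kendall_tau(x=x, y=y)
        assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_null_simulation(self):
        rng = np.random.default_rng(17)
        x, y = rng.lognormal(size=(2, 1000))
        tau, p = kendall_tau(x=x, y=y)
        assert abs(tau) < 0.08
        assert p > 0.01

    def test_minimum_pairs_enforced(self):
        with pytest.raises(UnsupportedDataError):
            kendall_tau(x=np.arange(5.0), y=np.arange(5.0))

    def test_censored_pairs_enter_at_limit(self):
        pairs = [(hv(v, v < 2), hv(2 * v, v < 1, analyte=Analyte.URANIUM))
                 for v in np.linspace(0.5, 10, 12)]
        x = np.array([a.value_ug_L for a, _ in pairs])
        y = np.array([u.value_ug_L for _, u in pairs])
        assert kendall_tau(pairs)[0] == pytest.approx(kendall_tau(x=x, y=y)[0])


class TestPetoPeto:
    def test_identical_groups_give_zero(self):
        g = hvs([1, 2, 3, 4, 5], [0, 0, 1, 0, 0])
        t = peto_peto_test(g, g)
        assert t.statistic == pytest.approx(0.0, abs=1e-12)
        assert t.p_value == pytest.approx(1.0)

    def test_separated_uncensored_groups(self):
        a = hvs([1, 2, 3, 4, 5], [0] * 5)
        b = hvs([10, 20, 30, 40, 50], [0] * 5)
        t = peto_peto_test(a, b)
        assert t.statistic > 6.0
        assert t.p_value < 0.01
        assert t.score > 0     # positive score identifies group_b as higher

    def test_frozen_censored_fixture(self):
        # frozen from an independent survival-analysis computation of the
        # rho=1 score test on the flipped sample
        a = hvs([1.2, 3.4, 2.0, 5.0, 1.0], [0, 0, 1, 0, 1])
        b = hvs([2.2, 6.1, 8.0, 4.0, 9.5], [0, 0, 0, 1, 0])
        t = peto_peto_test(a, b)
        assert t.statistic == pytest.approx(2.9615384615, abs=1e-9)
        assert t.p_value == pytest.approx(0.0852667753, abs=1e-9)

    def test_agrees_with_lifelines_peto_weighting(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 40)
        y = rng.lognormal(0.5, 1, 40)
        cx, cy = x < 0.8, y < 0.8
        xv, yv = np.where(cx, 0.8, x), np.where(cy, 0.8, y)
        mine = peto_peto_test(xv, yv, cx, cy)
        M = max(xv.max(), yv.max()) + 1.0
        ref = lifelines.statistics.logrank_test(
            M - xv, M - yv, event_observed_A=~cx, event_observed_B=~cy,
            weightings="peto")
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=0.02)

    def test_symmetry_under_group_swap(self):
        a = hvs([1.2, 3.4, 2.0, 5.0, 1.0], [0, 0, 1, 0, 1])
        b = hvs([2.2, 6.1, 8.0, 4.0, 9.5], [0, 0, 0, 1, 0])
        t1, t2 = peto_peto_test(a, b), peto_peto_test(b, a)
        assert t1.statistic == pytest.approx(t2.statistic, abs=1e-12)
        assert t1.score == pytest.approx(-t2.score, abs=1e-12)

    def test_invariant_to_flip_constant(self):
        a = hvs([1.2, 3.4, 2.0, 5.0, 1.0], [0, 0, 1, 0, 1])
        b = hvs([2.2, 6.1, 8.0, 4.0, 9.5], [0, 0, 0, 1, 0])
        t1 = peto_peto_test(a, b, flip_constant=10.0)
        t2 = peto_peto_test(a, b, flip_constant=1234.5)
        assert t1.statistic == pytest.approx(t2.statistic, abs=1e-9)

    def test_uncensored_score_is_rank_statistic(self):
        """With no censoring the score permutation-distributes like a rank sum.

        Over every assignment of 10 distinct values to two groups of five, the
        rho=1 score must be an affine function of the group-b rank sum, so an
        exhaustive permutation test on it is the exact Wilcoxon test.
        """
        values = np.array([3.0, 1.0, 7.0, 2.5, 9.0, 4.0, 8.0, 5.5, 0.7, 6.2])
        ranks = values.argsort().argsort() + 1
        scores, ranksums = [], []
        for idx_b in itertools.combinations(range(10), 5):
            mask = np.zeros(10, bool)
            mask[list(idx_b)] = True
            t = peto_peto_test(values[~mask], values[mask],
                               np.zeros(5, bool), np.zeros(5, bool))
            scores.append(t.score)
            ranksums.append(ranks[mask].sum())
        slope, intercept = np.polyfit(ranksums, scores, 1)
        assert np.asarray(scores) == pytest.approx(
            slope * np.asarray(ranksums) + intercept, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        ok = hvs([1, 2, 3, 4, 5], [0] * 5)
        with pytest.raises(UnsupportedDataError):
            peto_peto_test(ok, hvs([1, 2, 3], [0, 0, 0]))
        with pytest.raises(UnsupportedDataError):
            peto_peto_test(ok, hvs([2] * 5, [1] * 5))

    def test_type_one_error_small_sim(self):
        # smoke-scale null calibration; the full 1000-rep run lives in the
        # acceptance suite
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x, y = rng.lognormal(0, 1, (2, 50))
            cx, cy = x < 0.45, y < 0.45
            t = peto_peto_test(np.where(cx, 0.45, x), np.where(cy, 0.45, y), cx, cy)
            rejections += t.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestSummaries:
    def test_analyte_row_fields(self, config):
        vals = hvs([1.0, 12.0, 3.0, 15.0, 2.0, 0.5], [1, 0, 0, 0, 0, 1])
        row = summarize_analyte("overall", Analyte.ARSENIC, vals, config)
        assert row.n == 6
        assert row.detection_frequency == pytest.approx(4 / 6)
        assert row.frac_exceed_mcl == pytest.approx(2 / 6)
        assert row.ros_median is not None

    def test_joint_row_invariants(self, config):
        pairs = [(hv(a, a < 2, source_id=f"s{i}"),
                  hv(3 * a, a < 1, analyte=Analyte.URANIUM, source_id=f"s{i}"))
                 for i, a in enumerate(np.linspace(0.5, 30, 15))]
        row = summarize_joint("overall", pairs, config)
        assert row.frac_exceed_both <= row.frac_exceed_half_both
        assert row.tau is not None and -1 <= row.tau <= 1

    def test_sparse_stratum_marks_ros_unavailable(self, config):
        vals = hvs([1.0, 2.0, 0.5], [1, 1, 1])
        warnings = []
        row = summarize_analyte("tiny", Analyte.ARSENIC, vals, config, warnings)
        assert row.ros_median is None
        assert warnings and "ROS unavailable" in warnings[0]

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            ExceedanceSummary("s", "arsenic", 5, 0.5,
                              frac_exceed_half_both=0.1, frac_exceed_both=0.4)
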