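"""Log-linear growth model: stage summaries, fits, ratios, diagnostics."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from instarkit import (
    InsufficientDataError,
    StageSummary,
    ValidationError,
    brooks_ratios,
    dyar_report,
    missing_stage_check,
    ols_fit,
    stage_summaries,
    theil_sen_fit,
)


def pairwise_slope_median(points):
    """Independent oracle: enumerate pairwise slopes, take the median."""
    slopes = sorted(
        (b[1] - a[1]) / (b[0] - a[0])
        for a, b in itertools.combinations(points, 2)
        if a[0] != b[0]
    )
    m = len(slopes)
    return slopes[m // 2] if m % 2 else (slopes[m // 2 - 1] + slopes[m // 2]) / 2


class TestStageSummaries:
    def test_fossil_stage1_widths(self):
        s = stage_summaries([105.129, 115.993, 87.693, 115], [1, 1, 1, 1])
        assert s[0].mean == pytest.approx(105.954, abs=5e-4)
        assert s[0].n == 4 and not s[0].single_specimen

    def test_singleton_stage_uses_actual_value(self):
        (s,) = stage_summaries([418.808], [4])
        assert s.mean == 418.808 and s.single_specimen and s.sd is None

    def test_identical_values(self):
        (s,) = stage_summaries([100.0, 100.0], [2, 2])
        assert s.mean == 100.0 and s.sd == 0.0

    def test_empty_intermediate_stage_named(self):
        with pytest.raises(ValidationError, match="stage 2"):
            stage_summaries([1.0, 10.0], [1, 3])


class TestTheilSen:
    def test_exact_collinear(self):
        fit = theil_sen_fit([(1, 3), (2, 5), (3, 7), (4, 9)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_enumerated_three_points(self):
        # pairwise slopes {1, 4.5, 8} -> 4.5; intercepts {-3.5, -7, -3.5} -> -3.5
        fit = theil_sen_fit([(1, 1), (2, 2), (3, 10)])
        assert fit.slope == pytest.approx(4.5)
        assert fit.intercept == pytest.approx(-3.5)

    def test_duplicate_x_pairs_excluded(self):
        fit = theil_sen_fit([(1, 0), (1, 10), (2, 1), (3, 2)])
        assert math.isfinite(fit.slope)

    def test_all_slopes_undefined(self):
        with pytest.raises(InsufficientDataError):
            theil_sen_fit([(1, 0), (1, 1)])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        points=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=20),
                st.floats(min_value=-100, max_value=100, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_slope_matches_enumeration_oracle(self, points):
        xs = {p[0] for p in points}
        if len(xs) < 2:
            return
        fit = theil_sen_fit(points)
        assert fit.slope == pytest.approx(pairwise_slope_median(points))

    def test_slope_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        x = np.arange(1.0, 9.0)
        y = 0.7 * x + rng.normal(0, 0.3, x.size)
        fit = theil_sen_fit(list(zip(x, y)))
        ref = stats.theilslopes(y, x)
        assert fit.slope == pytest.approx(ref.slope)

    def test_robust_to_single_outlier(self):
        pts = [(i, 2.0 * i + 1.0) for i in range(1, 7)]
        clean = theil_sen_fit(pts).slope
        pts[5] = (6, 40.0)  # perturb one of six collinear points
        assert theil_sen_fit(pts).slope == pytest.approx(clean)


class TestOls:
    def test_hand_least_squares(self):
        fit = ols_fit([(1, 0), (2, 1), (3, 1)])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(-1 / 3)
        assert fit.r_squared == pytest.approx(0.75)

    def test_collinear_agrees_with_theil_sen(self):
        pts = [(1, 3), (2, 5), (3, 7)]
        a, b = ols_fit(pts), theil_sen_fit(pts)
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)
        assert a.r_squared == b.r_squared == pytest.approx(1.0)

    def test_residuals_sum_to_zero(self):
        fit = ols_fit([(1, 0.3), (2, 1.9), (3, 2.2), (4, 4.5)])
        assert float(np.sum(fit.residuals)) == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=-10, max_value=10, allow_nan=False),
        b=st.floats(min_value=0.01, max_value=10, allow_nan=False),
    )
    def test_r_squared_affine_invariant(self, a, b):
        pts = [(1, 0.3), (2, 1.9), (3, 2.2), (4, 4.5), (5, 4.1)]
        base = ols_fit(pts).r_squared
        scaled = ols_fit([(x, a + b * y) for x, y in pts]).r_squared
        assert scaled == pytest.approx(base)

    def test_too_few_distinct_x(self):
        with pytest.raises(InsufficientDataError):
            ols_fit([(1, 0), (1, 1)])


class TestBrooksRatios:
    def test_exact_geometric_series(self):
        s = stage_summaries([100.0, 200.0, 400.0], [1, 2, 3])
        br = brooks_ratios(s)
        assert br.ratios.tolist() == [0.5, 0.5]
        assert br.cv == 0.0
        assert np.allclose(br.growth_factors, [2.0, 2.0])

    def test_fossil_width_ratios(self, larvae_records):
        pairs = [
            (r.head_width, r.stage_label)
            for r in larvae_records
            if r.head_width is not None and r.stage_label is not None
        ]
        br = brooks_ratios(stage_summaries([v for v, _ in pairs], [s for _, s in pairs]))
        assert br.ratios == pytest.approx([0.632, 0.692, 0.579], abs=5e-4)
        assert br.mean_ratio == pytest.approx(0.634, abs=5e-4)

    def test_needs_two_stages(self):
        with pytest.raises(InsufficientDataError):
            brooks_ratios([StageSummary(1, 2, 100.0, 1.0, 99.0, 101.0)])


class TestGeometricSeriesIdentities:
    @pytest.mark.parametrize("r", [0.4, 0.6, 0.8])
    def test_slope_ratios_and_r2(self, r):
        """For means following m_{i+1} = m_i / r: slope = -ln r, R^2 = 1."""
        means = [100.0 / r ** (i - 1) for i in range(1, 6)]
        pts = [(float(i), math.log(m)) for i, m in enumerate(means, start=1)]
        for fit in (ols_fit(pts), theil_sen_fit(pts)):
            assert fit.slope == pytest.approx(-math.log(r))
            assert fit.r_squared == pytest.approx(1.0)
            assert fit.growth_ratio == pytest.approx(r)
        s = stage_summaries(means, list(range(1, 6)))
        assert brooks_ratios(s).ratios == pytest.approx([r] * 4)


class TestMissingStageCheck:
    def test_complete_geometric_series(self):
        pts = [(i, math.log(100.0 * 2 ** (i - 1))) for i in range(1, 5)]
        rep = missing_stage_check(ols_fit(pts))
        assert rep.verdict == "complete"
        assert np.allclose(rep.increments, math.log(2))

    def test_removed_stage_flagged(self):
        # ratio-2 series {100,200,400,800,1600} with the 400 stage removed:
        # increments {ln2, ln4, ln2, ln2}... relabelled 1..4 -> {ln2, ln4, ln2}
        # median ln2; ln4 = 2 x median exceeds the 1.5x threshold
        means = [100.0, 200.0, 800.0, 1600.0]
        pts = [(i, math.log(m)) for i, m in enumerate(means, start=1)]
        rep = missing_stage_check(ols_fit(pts))
        assert rep.verdict == "possibly-missing-stage"
        assert rep.flagged_after == [2]

    def test_three_stage_even_median_dilution(self):
        # with only two increments {ln4, ln2} the even-median convention gives
        # 1.5*ln2, so ln4 (= 4/3 of that) stays below the 1.5x threshold
        pts = [(1, math.log(100.0)), (2, math.log(400.0)), (3, math.log(800.0))]
        assert missing_stage_check(ols_fit(pts)).verdict == "complete"

    def test_fossil_width_series_complete(self, larvae_records):
        report = dyar_report(larvae_records, "head_width", "paper", "theil_sen")
        assert report["missing_stage"]["verdict"] == "complete"

    def test_needs_three_stages(self):
        with pytest.raises(InsufficientDataError):
            missing_stage_check(ols_fit([(1, 0.0), (2, 1.0)]))


class TestDyarReport:
    def test_paper_labels_head_width(self, larvae_records):
        report = dyar_report(larvae_records, "head_width", "paper", "theil_sen")
        assert report["n_stages"] == 4
        assert report["stage_sequence"] == [1, 2, 3, 4]
        assert report["stages"][3]["single_specimen"] is True
        assert round(report["brooks"]["mean_ratio"], 1) == 0.6

    def test_gap_labels_same_cohort_count(self, larvae_records):
        report = dyar_report(larvae_records, "head_width", "gaps", "theil_sen")
        assert report["n_stages"] == 4

    def test_head_length_r2_rounds_to_099_both_estimators(self, larvae_records):
        for method in ("theil_sen", "ols"):
            report = dyar_report(larvae_records, "head_length", "paper", method)
            assert round(report["r_squared"], 2) == 0.99

    def test_empty_label_set_errors(self):
        from instarkit import LarvalRecord

        with pytest.raises(ValidationError):
            dyar_report([LarvalRecord("X", head_width=100.0)], "head_width", "paper")
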