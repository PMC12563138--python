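"""Unit tests for trend fitting, segment selection, intersection and statuses."""

import math

import pytest

from breakeven import (
    BreakEvenConfig,
    HealingSeries,
    LinearTrend,
    Status,
    TimepointObservation,
    ValidationError,
    analyze_series,
    compare_materials,
    dimension_loss,
    estimate_break_even,
    fit_segment_trends,
    select_segment,
)


def obs(t, bone, graft, animal=None):
    return TimepointObservation(t, bone, graft, animal_id=animal)


def series_from_points(points, study="s", material="m"):
    return HealingSeries(study, material, [obs(*p) for p in points])


class TestObservationValidation:
    @pytest.mark.parametrize(
        "t,bone,graft",
        [(0.0, 10, 10), (-7, 10, 10), (7, -1, 10), (7, 101, 0), (7, 60, 50)],
    )
    def test_rejects_invalid_measurements(self, t, bone, graft):
        with pytest.raises(ValidationError):
            obs(t, bone, graft)

    def test_series_needs_two_distinct_times(self):
        with pytest.raises(ValidationError):
            series_from_points([(7, 1, 2), (7, 3, 4)])


class TestFitSegmentTrends:
    def test_autogenous_slopes(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Autogenous")]
        bone, graft = fit_segment_trends(s, (7, 35))
        assert bone.slope == pytest.approx(32.4 / 28)
        assert graft.slope == pytest.approx(-22.7 / 28)

    def test_genos_bone_slope(self, rabbit_series):
        s = rabbit_series[("Iida 2017", "Gen-Os")]
        bone, _ = fit_segment_trends(s, (14, 56))
        assert bone.slope == pytest.approx(20.55 / 42)

    def test_constant_series_is_flat(self):
        s = series_from_points([(10, 5, 50), (20, 5, 40)])
        bone, _ = fit_segment_trends(s, (10, 20))
        assert bone.slope == 0.0
        assert bone.intercept == 5.0

    def test_two_point_fit_is_exact_at_anchors(self, rabbit_series):
        s = rabbit_series[("Costa 2021", "Maxresorb")]
        bone, graft = fit_segment_trends(s, (14, 70))
        assert bone(14) == pytest.approx(2.65)
        assert bone(70) == pytest.approx(34.2)
        assert graft(14) == pytest.approx(52.05)
        assert graft(70) == pytest.approx(37.38)

    def test_unknown_time_is_input_error(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Autogenous")]
        with pytest.raises(ValidationError):
            fit_segment_trends(s, (7, 42))

    def test_duplicate_time_is_input_error(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Autogenous")]
        with pytest.raises(ValidationError):
            fit_segment_trends(s, (7, 7))


class TestSelectSegment:
    def test_two_timepoints_is_only_candidate(self, rabbit_series):
        s = rabbit_series[("Iida 2017", "Gen-Os")]
        assert select_segment(s) == (14, 56)

    def test_earliest_sign_change_wins(self):
        # bone - graft = (-30, -5, +10) at days 7/21/42 -> crossing in (21, 42)
        s = series_from_points([(7, 10, 40), (21, 20, 25), (42, 35, 25)])
        assert select_segment(s) == (21, 42)

    def test_no_sign_change_falls_back_to_last_pair(self):
        # bone - graft = (-30, -20, -5): crossing anticipated beyond the data
        s = series_from_points([(7, 10, 40), (21, 20, 40), (42, 35, 40)])
        assert select_segment(s) == (21, 42)

    def test_zero_difference_counts_as_crossing(self):
        s = series_from_points([(7, 10, 40), (21, 30, 30), (42, 45, 20)])
        assert select_segment(s) == (7, 21)


class TestEstimateBreakEven:
    def test_symmetric_lines_cross_at_midpoint(self):
        bone = LinearTrend(slope=10.0, intercept=0.0, t_start=1, t_end=10)
        graft = LinearTrend(slope=-10.0, intercept=100.0, t_start=1, t_end=10)
        r = estimate_break_even(bone, graft)
        assert r.time_days == pytest.approx(5.0)
        assert r.level_pct == pytest.approx(50.0)
        assert r.status is Status.WITHIN_INTERVAL

    def test_parallel_lines_are_divergent(self):
        bone = LinearTrend(1.0, 0.0, 1, 10)
        graft = LinearTrend(1.0, 50.0, 1, 10)
        r = estimate_break_even(bone, graft)
        assert r.status is Status.DIVERGENT
        assert r.time_days is None and r.level_pct is None

    def test_autogenous_within_interval(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Autogenous")]
        r = estimate_break_even(*fit_segment_trends(s, (7, 35)))
        assert r.time_days == pytest.approx(18.4, abs=0.05)
        assert r.level_pct == pytest.approx(13.5, abs=0.05)
        assert r.status is Status.WITHIN_INTERVAL

    def test_maxresorb_inject_extrapolated(self, rabbit_series):
        s = rabbit_series[("Costa 2021", "Maxresorb Inject")]
        r = estimate_break_even(*fit_segment_trends(s, (14, 70)))
        assert r.time_days == pytest.approx(96.1, abs=0.05)
        assert r.level_pct == pytest.approx(34.1, abs=0.05)
        assert r.status is Status.EXTRAPOLATED
        assert r.extrapolation_factor == pytest.approx(96.148 / 70, abs=1e-3)

    def test_slow_bio_oss_not_reached_under_default_bound(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Bio-Oss")]
        r = estimate_break_even(*fit_segment_trends(s, (7, 180)))
        assert r.status is Status.NOT_REACHED
        assert r.time_days == pytest.approx(318, abs=0.5)

    def test_wider_bound_flips_not_reached_to_extrapolated(self, rabbit_series):
        s = rabbit_series[("Lambert 2011", "Bio-Oss")]
        cfg = BreakEvenConfig(max_extrapolation_factor=2.0)
        r = estimate_break_even(*fit_segment_trends(s, (7, 180)), cfg)
        assert r.status is Status.EXTRAPOLATED
        assert r.time_days == pytest.approx(318, abs=0.5)

    def test_crossing_before_segment_is_already_crossed(self):
        # bone already above graft at the first observation
        s = series_from_points([(10, 50, 20), (20, 60, 10)])
        r = analyze_series(s)
        assert r.status is Status.ALREADY_CROSSED

    def test_mismatched_segments_rejected(self):
        bone = LinearTrend(1.0, 0.0, 1, 10)
        graft = LinearTrend(-1.0, 50.0, 2, 10)
        with pytest.raises(ValidationError):
            estimate_break_even(bone, graft)


class TestDimensionLoss:
    @pytest.mark.parametrize(
        "a1,a2,expected", [(10.0, 5.0, 50.0), (10.0, 10.0, 0.0), (8.0, 9.2, -15.0)]
    )
    def test_loss_formula(self, a1, a2, expected):
        r = dimension_loss(a1, a2, 14, 70)
        assert r.loss_pct == pytest.approx(expected)
        assert r.period == (14, 70)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            dimension_loss(0.0, 5.0, 14, 70)


class TestAnalyzeSeries:
    @pytest.mark.parametrize(
        "key,days,level",
        [
            (("Iida 2017", "Gen-Os"), 40.4, 19.1),
            (("Yamada 2025", "Bio-Oss Collagen"), 62.3, 28.3),
            (("Costa 2021", "Maxresorb"), 73.85, 36.37),
        ],
    )
    def test_reproduces_published_estimates(self, rabbit_series, key, days, level):
        r = analyze_series(rabbit_series[key])
        assert r.time_days == pytest.approx(days, abs=0.05)
        assert r.level_pct == pytest.approx(level, abs=0.05)

    def test_maxresorb_is_flagged_extrapolated(self, rabbit_series):
        r = analyze_series(rabbit_series[("Costa 2021", "Maxresorb")])
        assert r.status is Status.EXTRAPOLATED

    def test_replicates_are_averaged_before_fitting(self):
        s = HealingSeries(
            "s",
            "m",
            [
                obs(10, 5, 45, "a1"),
                obs(10, 15, 55, "a2"),
                obs(30, 35, 15, "a1"),
                obs(30, 45, 25, "a2"),
            ],
        )
        mean_s = series_from_points([(10, 10, 50), (30, 40, 20)])
        r, r_mean = analyze_series(s), analyze_series(mean_s)
        assert r.time_days == pytest.approx(r_mean.time_days)
        assert r.level_pct == pytest.approx(r_mean.level_pct)


class TestCompareMaterials:
    def test_bundled_dataset_ordering(self, rabbit_table):
        df = compare_materials(rabbit_table.to_series())
        assert list(df["material"]) == [
            "Autogenous",
            "Gen-Os",
            "Bio-Oss Collagen",
            "Maxresorb",
            "Bio-Oss",
            "Maxresorb Inject",
            "Bio-Oss",
        ]
        assert df.iloc[-1]["status"] == "not_reached"
        assert df.iloc[-1]["study"] == "Lambert 2011"
        times = df["time_days"].iloc[:6]
        assert list(times) == sorted(times)

    def test_empty_input_gives_empty_table(self):
        assert compare_materials([]).empty

    def test_single_series_matches_analyze_series(self, rabbit_series):
        s = rabbit_series[("Iida 2017", "Gen-Os")]
        df = compare_materials([s])
        r = analyze_series(s)
        assert len(df) == 1
        assert df.iloc[0]["time_days"] == pytest.approx(r.time_days)
        assert df.iloc[0]["status"] == r.status.value


def test_result_consistency_between_trends(rabbit_series):
    """Both trend lines evaluate to the reported level at the crossing."""
    for s in rabbit_series.values():
        r = analyze_series(s)
        if not r.status.convergent:
            continue
        bone, graft = fit_segment_trends(s.aggregate(), r.segment)
        assert math.isclose(bone(r.time_days), graft(r.time_days), abs_tol=1e-9)
        assert math.isclose(bone(r.time_days), r.level_pct, abs_tol=1e-9)
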