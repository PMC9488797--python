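import numpy as np
import pandas as pd
import pytest

from isocal.qc import (
    QCConfig,
    RULE_DAY_INCOMPLETE,
    RULE_FOOD_SENTINEL,
    RULE_GAS_OUTLIER,
    RULE_INTAKE_OUTLIER,
    RULE_NEGATIVE,
    apply_point_rules,
    day_completeness_filter,
    drop_pre_zt0,
    run_qc,
)

from .conftest import make_trace_frame


class TestDropPreZT0:
    def test_trace_starting_at_zt0_unchanged(self):
        frame = make_trace_frame([{"t_min": m} for m in range(0, 240, 24)])
        out = drop_pre_zt0(frame)
        assert len(out) == len(frame)

    def test_pre_zt0_records_removed(self):
        # recording starts at ZT 20 of day 0: the ZT 20-24 records must go
        rows = [{"t_min": m} for m in range(-240, 240, 24)]
        frame = make_trace_frame(rows)
        out = drop_pre_zt0(frame)
        assert len(out) == 10
        assert out["zt"].iloc[0] == pytest.approx(0.0)

    def test_empty_input(self):
        frame = make_trace_frame([{"t_min": 0}]).iloc[0:0]
        assert drop_pre_zt0(frame).empty


class TestPointRules:
    def test_clean_fixture_unchanged(self):
        frame = make_trace_frame([{"food_g": 0.1 + 0.01 * i} for i in range(20)])
        out, report = apply_point_rules(frame)
        assert len(out) == 20
        assert all(v == 0 for v in report.rule_counts.values())

    def test_constructed_violations_each_counted_once(self):
        rows = [{"food_g": 0.10 + 0.005 * i, "water_g": 0.2} for i in range(17)]
        rows.append({"food_g": 0.01})  # balance noise sentinel
        rows.append({"water_g": -0.1})  # negative consumption
        rows.append({"food_g": 1.5})  # ~10x the median, leaky/spill outlier
        frame = make_trace_frame(rows)
        out, report = apply_point_rules(frame)
        assert len(out) == 17
        assert report.count(RULE_FOOD_SENTINEL) == 1
        assert report.count(RULE_NEGATIVE) == 1
        assert report.count(RULE_INTAKE_OUTLIER) == 1
        assert report.count(RULE_GAS_OUTLIER) == 0
        # conservation: every removed record attributed to exactly one rule
        assert report.input_count == report.surviving_count + report.total_removed

    def test_gas_outlier_rule(self):
        rows = [{"d_o2": 0.0030 + 0.0001 * (i % 5)} for i in range(19)]
        rows.append({"d_o2": 0.0002})  # clogged-filter collapse
        frame = make_trace_frame(rows)
        out, report = apply_point_rules(frame)
        assert report.count(RULE_GAS_OUTLIER) == 1
        assert len(out) == 19

    def test_degenerate_distribution_no_outliers(self):
        # identical food values: IQR = 0, threshold = Q75, nothing above it
        frame = make_trace_frame([{"food_g": 0.2} for _ in range(10)])
        out, report = apply_point_rules(frame)
        assert report.count(RULE_INTAKE_OUTLIER) == 0
        assert len(out) == 10

    def test_first_rule_wins_attribution(self):
        # a record that is both the sentinel and negative dO2 counts as sentinel
        rows = [{"food_g": 0.1} for _ in range(10)]
        rows.append({"food_g": 0.01, "d_o2": -0.001})
        frame = make_trace_frame(rows)
        _, report = apply_point_rules(frame)
        assert report.count(RULE_FOOD_SENTINEL) == 1
        assert report.count(RULE_NEGATIVE) == 0

    def test_too_few_records_skips_quartiles(self):
        frame = make_trace_frame([{"food_g": 5.0}, {"food_g": 0.1}, {"food_g": 0.1}])
        out, report = apply_point_rules(frame)
        assert "m1" in report.quartiles_skipped
        assert len(out) == 3  # quartile rules skipped, nothing removed

    def test_idempotent_with_fixed_thresholds(self, small_study):
        cfg = QCConfig()
        first, report = apply_point_rules(small_study.traces, cfg)
        second, report2 = apply_point_rules(first, cfg, thresholds=report.thresholds)
        assert len(second) == len(first)
        assert report2.total_removed == 0

    @pytest.mark.parametrize("k_low, k_high", [(1.0, 1.5), (1.5, 3.0)])
    def test_wider_fences_never_remove_more(self, small_study, k_low, k_high):
        _, low = apply_point_rules(small_study.traces, QCConfig(iqr_multiplier=k_low))
        _, high = apply_point_rules(small_study.traces, QCConfig(iqr_multiplier=k_high))
        assert high.total_removed <= low.total_removed
        assert high.count(RULE_INTAKE_OUTLIER) <= low.count(RULE_INTAKE_OUTLIER)
        assert high.count(RULE_GAS_OUTLIER) <= low.count(RULE_GAS_OUTLIER)


class TestDayCompleteness:
    def _day_with_missing(self, n_missing: int) -> pd.DataFrame:
        keep = range(n_missing, 60)  # drop the first n_missing slots of the day
        return make_trace_frame([{"t_min": 24 * i} for i in keep])

    def test_boundary_20_percent_retained(self):
        frame = self._day_with_missing(12)  # 12/60 = 20 %: not strictly greater
        out, report = day_completeness_filter(frame)
        assert len(out) == 48
        assert report.count(RULE_DAY_INCOMPLETE) == 0

    def test_just_over_boundary_dropped(self):
        frame = self._day_with_missing(13)  # 13/60 > 20 %
        out, report = day_completeness_filter(frame)
        assert out.empty
        assert report.count(RULE_DAY_INCOMPLETE) == 47
        assert report.dropped_days["removed_fraction"].iloc[0] == pytest.approx(13 / 60)

    def test_complete_day_retained(self):
        frame = self._day_with_missing(0)
        out, report = day_completeness_filter(frame)
        assert len(out) == 60
        assert report.dropped_days.empty


class TestFullChain:
    def test_conservation_bookkeeping(self, small_study):
        clean, report = run_qc(small_study.traces)
        assert report.input_count == len(small_study.traces)
        assert report.surviving_count == len(clean)
        assert report.input_count == report.surviving_count + report.total_removed

    def test_injected_sentinel_and_negative_faults_all_caught(self, small_study):
        _, report = run_qc(small_study.traces)
        removed = report.removed[["mouse_id", "timestamp", "rule"]]
        log = small_study.fault_log
        for rule in (RULE_FOOD_SENTINEL, RULE_NEGATIVE):
            injected = log[log["expected_rule"] == rule]
            hit = injected.merge(removed, on=["mouse_id", "timestamp"], how="left")
            assert hit["rule"].notna().all(), f"missed {rule} faults"

    def test_quantile_fault_recall_high(self, small_study):
        _, report = run_qc(small_study.traces)
        removed = report.removed[["mouse_id", "timestamp", "rule"]]
        log = small_study.fault_log
        quant = log[log["expected_rule"].isin([RULE_INTAKE_OUTLIER, RULE_GAS_OUTLIER])]
        hit = quant.merge(removed, on=["mouse_id", "timestamp"], how="left")
        assert hit["rule"].notna().mean() >= 0.9
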