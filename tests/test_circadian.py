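import numpy as np
import pandas as pd
import pytest

from isocal.circadian import (
    auc_trapezoid,
    cumulative_intake,
    per_timepoint_means,
    smooth_circadian,
    summarize_phases,
)
from isocal.gas import add_exchange
from isocal.io import add_time_axis
from isocal.qc import run_qc


class TestAUC:
    def test_constant_over_span(self):
        t = np.arange(0.0, 12.1, 0.4)
        assert auc_trapezoid(t, np.full_like(t, 3.0), (0, 12)) == pytest.approx(36.0)

    def test_triangle(self):
        assert auc_trapezoid([0, 1, 2], [0, 1, 0], (0, 2)) == pytest.approx(1.0)

    def test_linear_ramp_exact(self):
        t = np.linspace(0, 10, 7)
        v = 2.0 * t + 1.0
        assert auc_trapezoid(t, v, (0, 10)) == pytest.approx(110.0)

    def test_window_edges_interpolated(self):
        # series spans [0, 4]; window [1, 3) uses interpolated edge values
        t = np.array([0.0, 2.0, 4.0])
        v = np.array([0.0, 2.0, 0.0])
        assert auc_trapezoid(t, v, (1.0, 3.0)) == pytest.approx(3.0)

    def test_too_few_points_is_missing(self):
        assert np.isnan(auc_trapezoid([5.0], [1.0], (0, 12)))

    def test_gap_bridged_by_single_trapezoid(self):
        # points removed between t=2 and t=8: one trapezoid spans the gap
        t = np.array([0.0, 2.0, 8.0, 10.0])
        v = np.array([1.0, 1.0, 1.0, 1.0])
        assert auc_trapezoid(t, v, (0, 10)) == pytest.approx(10.0)


class TestCumulativeIntake:
    def test_empty_window(self):
        assert cumulative_intake([1, 2, 3], [0.2, 0.2, 0.2], (10, 12)) == 0.0

    def test_sum(self):
        assert cumulative_intake([1, 2, 3], [0.2, 0.2, 0.2], (0, 4)) == pytest.approx(0.6)

    def test_partition_additivity(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 24, 0.4)
        g = rng.gamma(2.0, 0.05, t.size)
        total = cumulative_intake(t, g, (0, 24))
        parts = cumulative_intake(t, g, (0, 12)) + cumulative_intake(t, g, (12, 24))
        assert parts == pytest.approx(total)


@pytest.fixture(scope="module")
def summaries(noiseless_study):
    clean, _ = run_qc(noiseless_study.traces)
    annotated = add_exchange(clean)
    return annotated, summarize_phases(annotated)


class TestSummaries:

    def test_light_plus_dark_equals_full_day(self, summaries):
        _, summ = summaries
        wide = summ.pivot_table(
            index=["mouse_id", "day"], columns="phase", values="ee_kcal"
        )
        interior = wide.dropna()
        np.testing.assert_allclose(
            interior["light"] + interior["dark"], interior["full_day"], rtol=1e-9
        )

    def test_phase_aucs_match_generator_integrals(self, noiseless_study, summaries):
        # the latent EE rate is ee_daily/1440 * (1 + a*cos(2pi(zt-18)/24));
        # its analytic integral over interior full days is ee_daily
        _, summ = summaries
        truth = noiseless_study.truth["per_mouse"].set_index("mouse_id")
        interior = summ[(summ["phase"] == "full_day") & (summ["day"] < 2)]
        for _, row in interior.iterrows():
            latent = truth.loc[row["mouse_id"], "latent_ee_kcal_day"]
            assert row["ee_kcal"] == pytest.approx(latent, rel=0.005)

    def test_rer_mean_of_constant_trace_is_constant(self):
        t_min = np.arange(0, 24 * 60, 24)
        frame = pd.DataFrame(
            {
                "mouse_id": "m1",
                "t_h": t_min / 60.0,
                "day": 0,
                "ee_kcal_min": 0.006,
                "rer": 0.85,
                "h2_rate": 0.0,
                "food_g": 0.0,
            }
        )
        summ = summarize_phases(frame)
        np.testing.assert_allclose(summ["rer_mean"], 0.85)

    def test_day_dropped_by_qc_has_no_row(self, small_study):
        clean, report = run_qc(small_study.traces)
        summ = summarize_phases(add_exchange(clean))
        present = set(zip(summ["mouse_id"], summ["day"]))
        for _, row in report.dropped_days.iterrows():
            assert (row["mouse_id"], row["day"]) not in present


class TestSpline:
    def test_noiseless_cubic_recovered(self):
        x = np.linspace(0, 24, 40)
        y = 1.0 + 0.1 * x - 0.01 * x**2 + 0.0005 * x**3
        curve = smooth_circadian(x, y, cyclic=False)
        truth = 1.0 + 0.1 * curve.grid - 0.01 * curve.grid**2 + 0.0005 * curve.grid**3
        assert np.max(np.abs(curve.fitted - truth)) < 1e-6

    def test_noisy_sinusoid_recovered(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 24, 60, endpoint=False)
        truth = np.sin(2 * np.pi * x / 24)
        y = truth + rng.normal(0, 0.01, x.size)
        curve = smooth_circadian(x, y, cyclic=True)
        fitted_truth = np.sin(2 * np.pi * curve.grid / 24)
        assert np.max(np.abs(curve.fitted - fitted_truth)) < 0.05

    def test_constant_data_constant_fit(self):
        x = np.linspace(0, 24, 30, endpoint=False)
        curve = smooth_circadian(x, np.full(30, 2.5))
        np.testing.assert_allclose(curve.fitted, 2.5, rtol=1e-8)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 24, 48, endpoint=False)
        y = np.cos(2 * np.pi * x / 24) + rng.normal(0, 0.05, x.size)
        c0 = smooth_circadian(x, y)
        c1 = smooth_circadian(x, y + 10.0)
        np.testing.assert_allclose(c1.fitted - c0.fitted, 10.0, atol=1e-6)

    def test_needs_ten_distinct_timepoints(self):
        with pytest.raises(ValueError):
            smooth_circadian(np.arange(5.0), np.arange(5.0))


def test_per_timepoint_averaging_precedes_smoothing(small_study):
    clean, _ = run_qc(small_study.traces)
    ann = add_exchange(clean)
    means = per_timepoint_means(ann, "rer")
    # one row per mouse x zt, i.e. days averaged away within mouse first
    assert means.groupby(["mouse_id", "zt"]).size().max() == 1
    m = means[means["mouse_id"] == means["mouse_id"].iloc[0]]
    manual = (
        ann[ann["mouse_id"] == m["mouse_id"].iloc[0]].groupby("zt")["rer"].mean()
    )
    got = m.set_index("zt")["mean_value"]
    np.testing.assert_allclose(got.sort_index(), manual.sort_index())
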