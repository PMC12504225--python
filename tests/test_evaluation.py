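"""Metrics, percent improvements, peak/valley analysis, aggregation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gait_ssl as g
from gait_ssl.errors import IncompleteResultError, InvalidArgumentError, SchemaError
from gait_ssl.evaluation import (
    REFERENCE_EFFICIENCY_50PCT_PAIR,
    REFERENCE_MSE_PAIRS,
    REFERENCE_RKNEE_MAE_PAIR,
    CrossJointMatrix,
    compute_report,
)


def _loop_mse(y, y_hat):
    total = 0.0
    for a, b in zip(y, y_hat):
        total += (a - b) ** 2
    return total / len(y)


def _loop_mae(y, y_hat):
    total = 0.0
    for a, b in zip(y, y_hat):
        total += abs(a - b)
    return total / len(y)


class TestScalarMetrics:
    def test_identity_gives_zero(self):
        x = np.arange(10.0)
        assert g.mse(x, x) == 0.0
        assert g.mae(x, x) == 0.0

    def test_hand_computed_examples(self):
        assert g.mse([0, 0], [1, 3]) == pytest.approx(5.0)
        assert g.mae([0, 0], [1, 3]) == pytest.approx(2.0)

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 1000))
            y = rng.normal(size=n)
            y_hat = rng.normal(size=n)
            assert g.mse(y, y_hat) == pytest.approx(_loop_mse(y, y_hat), abs=1e-12)
            assert g.mae(y, y_hat) == pytest.approx(_loop_mae(y, y_hat), abs=1e-12)

    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=2**31 - 1))
    def test_jensen_inequality(self, n, seed):
        rng = np.random.default_rng(seed)
        y, y_hat = rng.normal(size=n), rng.normal(size=n)
        assert g.mae(y, y_hat) <= np.sqrt(g.mse(y, y_hat)) + 1e-12

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.mse([1, 2], [1])
        with pytest.raises(InvalidArgumentError):
            g.mae([], [])


class TestPercentImprovement:
    def test_reference_mse_pairs_reproduce_reported_percentages(self):
        """The published per-joint MSE pairs recompute to the reported
        one-decimal improvement figures."""
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["LAnkleFlex"]) == 38.9
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["RAnkleFlex"]) == 33.3
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["RKneeFlex"]) == 44.4
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["LHipFlex"]) == 45.2
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["LKneeFlex"], decimals=0) == 32
        assert g.percent_improvement(*REFERENCE_MSE_PAIRS["RHipFlex"], decimals=0) == 24

    def test_mae_and_efficiency_pairs(self):
        assert g.percent_improvement(*REFERENCE_RKNEE_MAE_PAIR, decimals=0) == 24
        assert g.percent_improvement(*REFERENCE_EFFICIENCY_50PCT_PAIR, decimals=2) == 44.44

    def test_no_improvement_is_zero(self):
        assert g.percent_improvement(0.3, 0.3) == 0.0

    def test_invalid_baseline_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.percent_improvement(0.0, 0.1)
        with pytest.raises(InvalidArgumentError):
            g.percent_improvement(0.1, -0.1)


class TestImprovementSummary:
    def test_six_reference_pairs_summarize_to_reported_statistics(self):
        pairs = list(REFERENCE_MSE_PAIRS.values())
        lo, hi, mean = g.improvement_summary(pairs)
        assert (lo, hi) == (24.00, 45.16)
        assert mean == 36.29

    def test_single_pair_degenerates(self):
        lo, hi, mean = g.improvement_summary([(0.04, 0.03)])
        assert lo == hi == mean == 25.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.improvement_summary([])


class TestPeakValleyReport:
    def test_perfect_prediction_has_zero_errors(self):
        t = np.arange(100)
        obs = np.sin(2 * np.pi * t / 100)
        table = g.peak_valley_report(obs, obs)
        assert len(table) > 0
        np.testing.assert_allclose(table["abs_error"], 0.0)
        np.testing.assert_allclose(table["rel_error_pct"], 0.0)

    def test_uniform_shrinkage_gives_uniform_relative_error(self):
        t = np.arange(100)
        obs = np.sin(2 * np.pi * t / 100)
        table = g.peak_valley_report(obs, 0.9 * obs)
        np.testing.assert_allclose(table["rel_error_pct"], 10.0, rtol=1e-9)

    def test_sine_extrema_located_at_quarter_cycles(self):
        t = np.arange(100)
        obs = np.sin(2 * np.pi * t / 100)
        table = g.peak_valley_report(obs, obs)
        peaks = table[table["kind"] == "peak"]["location_pct"].tolist()
        valleys = table[table["kind"] == "valley"]["location_pct"].tolist()
        assert peaks == [25.0]
        assert valleys == [75.0]

    def test_flat_curve_warns_and_returns_empty(self):
        flat = np.zeros(50)
        with pytest.warns(UserWarning, match="extrema"):
            table = g.peak_valley_report(flat, flat)
        assert table.empty


class TestAggregateRuns:
    def _report(self, mse_val, seed):
        obs = np.zeros((4, 10, 1))
        pred = np.full_like(obs, np.sqrt(mse_val))
        return compute_report(obs, pred, ["LKneeFlex"], seed=seed)

    def test_single_report_is_identity(self):
        rep = self._report(0.04, seed=0)
        agg = g.aggregate_runs([rep])
        assert agg.mse == rep.mse

    def test_mean_of_two_reports(self):
        agg = g.aggregate_runs([self._report(0.02, 0), self._report(0.04, 1)])
        assert agg.mse["LKneeFlex"] == pytest.approx(0.03)
        assert agg.seeds == [0, 1]
        assert agg.per_seed_mse["LKneeFlex"] == pytest.approx([0.02, 0.04])

    def test_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.01, 0.1, size=7)
        agg = g.aggregate_runs([self._report(v, i) for i, v in enumerate(vals)])
        assert agg.mse["LKneeFlex"] == pytest.approx(sum(vals) / len(vals), rel=1e-9)

    def test_heterogeneous_reports_rejected(self):
        a = self._report(0.02, 0)
        b = self._report(0.02, 1)
        b.mse = {"Other": 0.02}
        with pytest.raises(SchemaError):
            g.aggregate_runs([a, b])

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.aggregate_runs([])


class TestComputeReport:
    def test_jensen_holds_per_joint(self, tiny_dataset):
        ws = g.prepare_windows(tiny_dataset, window=32, step=8)
        rng = np.random.default_rng(0)
        pred = ws.targets + rng.normal(scale=0.05, size=ws.targets.shape)
        rep = compute_report(ws.targets, pred, ws.target_names)
        for j in ws.target_names:
            assert rep.mae[j] ** 2 <= rep.mse[j] + 1e-12
            assert rep.per_timestep[j].shape == (32,)


class TestCrossJointMatrixContainer:
    def test_shape_and_negativity_guards(self):
        with pytest.raises(SchemaError):
            CrossJointMatrix(values=np.zeros((5, 6)))
        with pytest.raises(IncompleteResultError):
            CrossJointMatrix(values=np.full((6, 6), -1.0))

    def test_diagonal_row_minima_counting(self):
        vals = np.ones((6, 6)) + np.eye(6) * -0.5  # diagonal strictly smallest
        assert CrossJointMatrix(values=vals).diagonal_row_minima() == 36
        vals[0, 1] = 0.1  # one off-diagonal dips below the diagonal
        assert CrossJointMatrix(values=vals).diagonal_row_minima() == 35


class TestEfficiencyCurveContainer:
    def test_degenerate_single_fraction_single_seed(self):
        curve = g.EfficiencyCurve(
            fractions=[1.0],
            ssl=np.array([0.02]),
            baseline=np.array([0.03]),
            ssl_per_seed=np.array([[0.02]]),
            baseline_per_seed=np.array([[0.03]]),
            seeds=[0],
        )
        df = curve.to_dataframe()
        assert set(df["arm"]) == {"ssl", "baseline"}
        assert len(df) == 2

    def test_unsorted_fractions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.EfficiencyCurve(
                fractions=[1.0, 0.2],
                ssl=np.zeros(2),
                baseline=np.zeros(2),
                ssl_per_seed=np.zeros((2, 1)),
                baseline_per_seed=np.zeros((2, 1)),
                seeds=[0],
            )

    def test_missing_arm_detected(self):
        with pytest.raises(IncompleteResultError):
            g.EfficiencyCurve(
                fractions=[0.2, 1.0],
                ssl=np.zeros(2),
                baseline=np.zeros(2),
                ssl_per_seed=np.array([[0.1], [np.nan]]),
                baseline_per_seed=np.zeros((2, 1)),
                seeds=[0],
            )
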