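import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogate import simulate as sim
from cytogate.validation import (
    StatError,
    absolute_difference,
    build_report,
    f_measure,
    icc_mixed_model,
    optimization_gate,
    pearson_ci,
    percent_bias,
    remove_outliers,
)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_ci(np.column_stack([x, 2 * x]))
        assert r == pytest.approx(1.0)

    def test_null_is_small(self):
        rng = np.random.default_rng(0)
        r, _, _ = pearson_ci(rng.normal(size=(1000, 2)))
        assert abs(r) < 0.1

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        r, lo, hi = pearson_ci(np.column_stack([x, y]))
        assert lo < r < hi
        # Fisher z interval, computed independently
        z = np.arctanh(r)
        se = 1 / np.sqrt(200 - 3)
        assert lo == pytest.approx(np.tanh(z - 1.959964 * se), abs=1e-6)

    def test_preconditions(self):
        with pytest.raises(StatError):
            pearson_ci(np.ones((3, 2)))
        with pytest.raises(StatError):
            pearson_ci(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestPercentBias:
    def test_identical_methods_zero(self):
        x = np.random.default_rng(2).uniform(1, 5, 50)
        bias, lo, hi = percent_bias(np.column_stack([x, x]))
        assert bias == 0.0

    def test_scaling_gives_ten_percent(self):
        x = np.random.default_rng(3).uniform(1, 5, 50)
        bias, _, _ = percent_bias(np.column_stack([1.1 * x, x]))
        assert bias == pytest.approx(10.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        pairs = rng.uniform(1, 5, size=(40, 2))
        b1, _, _ = percent_bias(pairs, seed=7)
        b2, _, _ = percent_bias(pairs * 3.7, seed=7)
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_zero_manual_errors(self):
        with pytest.raises(StatError):
            percent_bias(np.column_stack([np.ones(5), np.zeros(5)]))

    def test_bootstrap_ci_brackets_estimate(self):
        pc = sim.generate_paired_counts(bias=0.9, n_samples=200, seed=5)
        est, lo, hi = percent_bias(pc[["hybrid", "manual"]].to_numpy(), seed=5)
        assert lo < est < hi


class TestAbsoluteDifference:
    @pytest.mark.parametrize("a,b,signed,absolute", [
        ([1, 2], [2, 1], 0.0, 1.0),
        ([3], [1], 2.0, 2.0),
        ([1.5, 2.5], [1.5, 2.5], 0.0, 0.0),
    ])
    def test_worked_values(self, a, b, signed, absolute):
        s, ab = absolute_difference(np.column_stack([a, b]))
        assert s == pytest.approx(signed)
        assert ab == pytest.approx(absolute)


class TestFMeasure:
    def test_printed_formula_worked_example(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 0.6667
        a = np.array([1, 1, 1, 0, 0], dtype=bool)
        b = np.array([1, 1, 0, 1, 0], dtype=bool)
        assert f_measure(a, b) == pytest.approx(2 / 3, abs=1e-12)

    def test_identical_masks(self):
        a = np.array([1, 0, 1], dtype=bool)
        assert f_measure(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.array([1, 0], dtype=bool)
        assert f_measure(a, ~a) == 0.0

    def test_empty_empty_convention(self):
        z = np.zeros(5, dtype=bool)
        assert f_measure(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(StatError):
            f_measure(np.zeros(3, bool), np.zeros(4, bool))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_confusion_matrix_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 200)
        a = rng.random(n) < rng.random()
        b = rng.random(n) < rng.random()
        tp = sum(1 for i in range(n) if a[i] and b[i])
        fp = sum(1 for i in range(n) if a[i] and not b[i])
        fn = sum(1 for i in range(n) if not a[i] and b[i])
        expected = 1.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
        assert f_measure(a, b) == pytest.approx(expected, abs=1e-15)


class TestRemoveOutliers:
    def test_single_far_point_removed(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, 99)
        pairs = np.column_stack([np.append(vals, 1000.0),
                                 np.append(vals, 0.0)])
        # brute-force 3-SD rule
        expected = np.abs(pairs - pairs.mean(0)) > 3 * pairs.std(0, ddof=1)
        kept, n_removed = remove_outliers(pairs)
        assert n_removed == int(expected.any(axis=1).sum()) == 1

    def test_all_equal_removes_none(self):
        pairs = np.ones((20, 2))
        _, n = remove_outliers(pairs)
        assert n == 0

    def test_either_method_rule(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        a[0] = 100.0  # outlying only in the automated column
        kept, n = remove_outliers(np.column_stack([a, b]))
        assert n == 1
        assert 100.0 not in kept[:, 0]

    def test_no_outliers_leaves_r_unchanged(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 50)
        pairs = np.column_stack([x, x + rng.uniform(0, 0.1, 50)])
        kept, n = remove_outliers(pairs)
        if n == 0:
            assert pearson_ci(kept)[0] == pearson_ci(pairs)[0]

    def test_never_increases_n(self):
        rng = np.random.default_rng(9)
        pairs = rng.normal(size=(30, 2))
        kept, _ = remove_outliers(pairs)
        assert kept.shape[0] <= 30


class TestOptimizationGate:
    @pytest.mark.parametrize("r,expected", [
        (0.76, True), (0.75, False), (-0.2, False), (1.0, True), (0.7500001, True),
    ])
    def test_strict_threshold(self, r, expected):
        assert optimization_gate(r) is expected

    def test_nan_rejected(self):
        with pytest.raises(StatError):
            optimization_gate(float("nan"))


class TestIcc:
    def test_parameter_recovery_pooled(self):
        """Variance components recover (0.5, 0.5); the pooled ICC over
        replications sits within 0.03 of the true 0.5."""
        vis, ves = [], []
        for s in range(40):
            d = sim.generate_technician_study(0.5, 0.5, seed=s)
            _, vi, ve = icc_mixed_model(d)
            vis.append(vi)
            ves.append(ve)
        pooled = np.mean(vis) / (np.mean(vis) + np.mean(ves))
        assert pooled == pytest.approx(0.5, abs=0.05)
        assert np.mean(ves) == pytest.approx(0.5, abs=0.05)

    def test_null_inter_variance(self):
        iccs = [icc_mixed_model(
            sim.generate_technician_study(0.0, 1.0, seed=100 + s))[0]
            for s in range(30)]
        assert np.mean(np.array(iccs) <= 0.05) >= 0.9

    def test_matches_anova_on_balanced_design(self):
        """REML agrees with the method-of-moments ANOVA estimator."""
        d = sim.generate_technician_study(1.0, 0.5, n_reps=6, seed=3)
        _, vi, ve = icc_mixed_model(d)
        # ANOVA oracle: technician mean square on a balanced crossed design
        c = d["control_id"].nunique()
        r = len(d) // (c * d["technician_id"].nunique())
        tech_means = d.groupby("technician_id")["value"].mean()
        ms_tech = c * r * tech_means.var(ddof=1)
        ve_hat = d.groupby(["technician_id", "control_id"])["value"] \
            .var(ddof=1).mean()
        vi_hat = max((ms_tech - ve_hat) / (c * r), 0.0)
        assert ve == pytest.approx(ve_hat, rel=0.1)
        assert vi == pytest.approx(vi_hat, rel=0.1)

    def test_single_technician_errors(self):
        d = sim.generate_technician_study(0.5, 0.5, n_technicians=1, seed=0)
        with pytest.raises(StatError):
            icc_mixed_model(d)


class TestBuildReport:
    def test_constant_population_gets_reason_code(self):
        paired = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)] * 2,
            "population": ["good_pop"] * 20 + ["flat_pop"] * 20,
            "hybrid": list(np.linspace(1, 3, 20)) + [1.0] * 20,
            "manual": list(np.linspace(1.1, 3.2, 20)) + [1.0] * 20,
        })
        report = build_report(paired)
        flat = report.table.set_index("population").loc["flat_pop"]
        assert flat["reason"] != ""
        good = report.table.set_index("population").loc["good_pop"]
        assert good["r"] > 0.99

    def test_csv_round_trip(self, tmp_path):
        pc = sim.generate_paired_counts(bias=0.9, n_samples=60, seed=11)
        report = build_report(pc[["sample_id", "population", "hybrid", "manual"]])
        p = tmp_path / "report.csv"
        report.to_csv(p)
        back = pd.read_csv(p)
        assert back.loc[0, "r"] == pytest.approx(report.table.loc[0, "r"])
        assert back.loc[0, "percent_bias"] == pytest.approx(
            report.table.loc[0, "percent_bias"])

    def test_report_contains_pre_and_post_outlier_r(self):
        pc = sim.generate_paired_counts(bias=1.0, n_samples=60, seed=12)
        report = build_report(pc[["sample_id", "population", "hybrid", "manual"]])
        row = report.table.iloc[0]
        assert not np.isnan(row["r"])
        assert not np.isnan(row["r_after_outlier_removal"])
        assert row["n_outliers_removed"] >= 0

    def test_f_measure_and_design_integration(self):
        rng = np.random.default_rng(13)
        masks = {"pop": (rng.random(500) < 0.3, rng.random(500) < 0.3)}
        pc = sim.generate_paired_counts(n_samples=30, population="pop", seed=14)
        design = sim.generate_technician_study(0.3, 0.7, population="pop", seed=15)
        report = build_report(
            pc[["sample_id", "population", "hybrid", "manual"]],
            masks=masks, design=design)
        row = report.table.iloc[0]
        assert 0 <= row["f_measure"] <= 1
        assert 0 <= row["icc"] <= 1
        assert "| pop |" in report.to_markdown()
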