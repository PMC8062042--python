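"""Correlation reports, Spearman analysis and worker statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from airwaycrowd.evaluation import (
    bonferroni_threshold,
    correlation_table,
    expert_measure_table,
    interpret_strength,
    pearson,
    per_subject_correlations,
    quality_prediction,
    spearman_pvalue,
    spearman_with_p,
    threshold_sweep,
    worker_statistics,
)


class TestPearson:
    def test_perfect_linear(self):
        x = [1, 2, 3, 4]
        assert pearson(x, [2 * v + 3 for v in x]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1, 2, 3, 4]
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_reported_missing_not_zero(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_nan_pairs_dropped(self):
        rho = pearson([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 1])
        assert rho == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        assert pearson(3 * x + 7, -2 * y + 1) == pytest.approx(-pearson(x, y))
        assert pearson(3 * x + 7, 2 * y + 1) == pytest.approx(pearson(x, y))


class TestStrengthBands:
    @pytest.mark.parametrize(
        "rho,band",
        [(0.0, "weak"), (0.29, "weak"), (0.3, "moderate"), (0.49, "moderate"),
         (0.5, "strong"), (1.0, "strong"), (-0.6, "strong")],
    )
    def test_half_open_bands(self, rho, band):
        assert interpret_strength(rho) == band

    def test_nan_is_undefined(self):
        assert interpret_strength(float("nan")) == "undefined"


class TestSpearman:
    def test_monotone_nonlinear_gives_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rho, p = spearman_with_p(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_binary_covariate_through_tied_ranks(self):
        x = [0, 0, 0, 1, 1, 1]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rho, p = spearman_with_p(x, y)
        assert np.isfinite(rho) and np.isfinite(p)
        assert rho > 0.8

    def test_matches_scipy_on_random_data(self, rng):
        """Dual route: our rank + t-approximation vs scipy.stats.spearmanr."""
        for _ in range(20):
            x = rng.normal(size=24)
            y = 0.4 * x + rng.normal(size=24)
            rho, p = spearman_with_p(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_printed_study_pvalue_reproduced(self):
        """rho_s = -0.265 at n = 24 gives p close to the reported 0.211."""
        assert spearman_pvalue(-0.265, 24) == pytest.approx(0.211, abs=0.02)

    def test_all_tied_input_undefined(self):
        rho, p = spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_type_one_error_calibrated_at_n24(self, rng):
        """Null rejection rate at alpha=0.05 stays in [0.03, 0.07] (n=24)."""
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            _, p = spearman_with_p(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestQualityPrediction:
    @pytest.fixture
    def subjects(self, rng):
        n = 24
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "has_cf": rng.integers(0, 2, n),
                "fev1": rng.normal(90, 15, n),
                "fvc": rng.normal(95, 15, n),
                "n_airways": rng.integers(18, 278, n),
                "mean_generation": rng.normal(6.5, 1, n),
            }
        )

    def test_adjusted_threshold_is_alpha_over_five(self, subjects, rng):
        quality = pd.Series(rng.uniform(0.5, 1.0, 24),
                            index=subjects["subject_id"])
        table = quality_prediction(subjects, quality)
        assert table.attrs["adjusted_alpha"] == pytest.approx(0.01)
        assert bonferroni_threshold(0.05, 5) == 0.01
        assert len(table) == 5

    def test_identical_characteristic_flagged_significant(self, subjects):
        quality = pd.Series(subjects["fev1"].to_numpy(),
                            index=subjects["subject_id"])
        table = quality_prediction(subjects, quality).set_index("characteristic")
        row = table.loc["fev1"]
        assert row["rho_s"] == pytest.approx(1.0)
        assert row["significant_raw"] and row["significant_adjusted"]

    def test_null_simulation_rarely_flags_multiple_tests(self, subjects, rng):
        """With no planted effect, <=1 of 5 tests hits p<0.05 in >=80% of reps."""
        ok = 0
        reps = 500
        for _ in range(reps):
            quality = pd.Series(rng.uniform(0.5, 1.0, 24),
                                index=subjects["subject_id"])
            table = quality_prediction(subjects, quality)
            ok += int(table["significant_raw"].sum() <= 1)
        assert ok / reps >= 0.80

    def test_missing_covariates_drop_subject(self, subjects, rng):
        subjects = subjects.copy()
        subjects.loc[0, "fev1"] = np.nan
        quality = pd.Series(rng.uniform(0.5, 1.0, 24),
                            index=subjects["subject_id"])
        table = quality_prediction(subjects, quality)
        assert (table["n_subjects"] == 23).all()


class TestWorkerStatistics:
    def test_all_valid_workers_sit_on_the_axis(self):
        labeled = pd.DataFrame(
            {"worker_id": ["w1"] * 3 + ["w2"] * 5, "status": ["valid"] * 8}
        )
        out = worker_statistics(labeled)
        assert (out["summaries"]["n_invalid"] == 0).all()
        assert np.isnan(out["fit"]["slope"])  # no spread in invalid counts

    def test_cumulative_curve_reaches_one(self, sim_labels):
        out = worker_statistics(sim_labels)
        cum = out["cumulative"]["cumulative_fraction"]
        assert cum.iloc[-1] == pytest.approx(1.0)
        assert cum.is_monotonic_increasing

    def test_counts_partition_per_worker(self, sim_labels):
        s = worker_statistics(sim_labels)["summaries"]
        assert (s["n_valid"] + s["n_invalid"] + s["n_multi_pair"] == s["n_results"]).all()
        assert s["n_results"].sum() == len(sim_labels)

    def test_fit_recovers_planted_valid_invalid_ratio(self, rng):
        """Workers with 60/40 valid/invalid mixes: slope near 1.5."""
        rows = []
        for w in range(300):
            n = int(rng.pareto(1.2) * 5) + 3
            n_valid = rng.binomial(n, 0.6)
            rows += [{"worker_id": f"w{w}", "status": "valid"}] * n_valid
            rows += [{"worker_id": f"w{w}", "status": "invalid"}] * (n - n_valid)
        out = worker_statistics(pd.DataFrame(rows))
        assert out["fit"]["slope"] == pytest.approx(1.5, rel=0.10)


class TestCorrelationTable:
    @pytest.fixture
    def expert_tbl(self):
        refs = pd.DataFrame(
            {
                "task_id": [f"t{i}" for i in range(30)] * 2,
                "expert_id": ["1"] * 30 + ["2"] * 30,
                "inner_area": list(np.linspace(5, 50, 30)) * 2,
                "outer_area": list(np.linspace(15, 90, 30)) * 2,
            }
        )
        return expert_measure_table(refs)

    def test_identical_crowd_gives_rho_one(self, expert_tbl):
        crowd = expert_tbl[expert_tbl["expert_id"] == "1"].drop(columns="expert_id")
        table = correlation_table({"median": crowd}, expert_tbl)
        crowd_rows = table[table["strategy"] == "median"]
        assert np.allclose(crowd_rows["rho"], 1.0)

    def test_expert_vs_expert_row_present(self, expert_tbl):
        table = correlation_table({}, expert_tbl)
        assert (table["strategy"] == "expert_1").any()

    def test_shuffled_pairing_kills_correlation(self, rng):
        n = 1000
        inner = rng.lognormal(1.5, 0.5, n)
        outer = inner * rng.uniform(1.5, 2.5, n)
        tasks = [f"t{i}" for i in range(n)]
        expert = expert_measure_table(
            pd.DataFrame({"task_id": tasks, "expert_id": "1",
                          "inner_area": inner, "outer_area": outer})
        )
        shuffled = expert.copy().drop(columns="expert_id")
        shuffled["task_id"] = rng.permutation(tasks)
        table = correlation_table({"median": shuffled}, expert)
        assert (table[table["strategy"] == "median"]["rho"].abs() < 0.1).all()


class TestThresholdSweep:
    def test_v1_equals_plain_median_combining(self, sim_measurements, sim_study):
        expert_tbl = expert_measure_table(
            pd.DataFrame(
                [
                    {"task_id": r.task_id, "expert_id": r.expert_id,
                     "inner_area": r.inner_area, "outer_area": r.outer_area}
                    for r in sim_study["experts"]
                ]
            )
        )
        sweep = threshold_sweep(sim_measurements, expert_tbl, [1, 5])
        from airwaycrowd.combining import Strategy, combine_dataset
        from airwaycrowd.evaluation import MEASURES, pearson as _p

        est = combine_dataset(sim_measurements, Strategy.MEDIAN, v=1)
        etab = expert_tbl[expert_tbl["expert_id"] == "1"]
        merged = est.merge(etab, on="task_id", suffixes=("_crowd", "_expert"))
        direct = _p(merged["inner_area_crowd"], merged["inner_area_expert"])
        row = sweep[(sweep["v"] == 1) & (sweep["measure"] == "inner")]
        assert row["rho"].iloc[0] == pytest.approx(direct)

    def test_retained_tasks_non_increasing_in_v(self, sim_measurements, sim_study):
        expert_tbl = expert_measure_table(
            pd.DataFrame(
                [
                    {"task_id": r.task_id, "expert_id": r.expert_id,
                     "inner_area": r.inner_area, "outer_area": r.outer_area}
                    for r in sim_study["experts"]
                ]
            )
        )
        sweep = threshold_sweep(sim_measurements, expert_tbl, range(1, 13))
        inner = sweep[sweep["measure"] == "inner"].sort_values("v")
        assert inner["n_tasks"].is_monotonic_decreasing


class TestPerSubject:
    def test_pooled_equals_per_subject_on_single_subject(self, rng):
        n = 40
        inner = rng.lognormal(1.5, 0.4, n)
        outer = inner * 1.8
        tasks = pd.DataFrame({"task_id": [f"t{i}" for i in range(n)],
                              "subject_id": "S0"})
        expert = expert_measure_table(
            pd.DataFrame({"task_id": tasks["task_id"], "expert_id": "1",
                          "inner_area": inner, "outer_area": outer})
        )
        crowd = expert.drop(columns="expert_id").copy()
        crowd["inner_area"] = inner * rng.lognormal(0, 0.1, n)
        table = per_subject_correlations(crowd, expert, tasks)
        assert len(table) == 1
        pooled = pearson(crowd["inner_area"], expert["inner_area"])
        assert table["inner"].iloc[0] == pytest.approx(pooled)
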