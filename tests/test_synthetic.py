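"""Synthetic cohort/crowd/expert generator contracts."""

import numpy as np
import pandas as pd
import pytest

from airwaycrowd.evaluation import expert_measure_table, pearson
from airwaycrowd.geometry import ImageFrame
from airwaycrowd.io import PipelineConfig
from airwaycrowd.measures import measure_result
from airwaycrowd.study import classify_results_table, tabulate_validity_from_frame
from airwaycrowd.synthetic import (
    Behavior,
    CohortConfig,
    CrowdConfig,
    WorkerProfile,
    generate_cohort,
    generate_workers,
    simulate_crowd,
    simulate_experts,
    simulate_study,
)

SMALL_COHORT = CohortConfig(n_subjects=4, tasks_per_subject=(8, 12))


class TestCohort:
    def test_contract_counts(self):
        truth, subjects = generate_cohort(1, CohortConfig(n_subjects=24))
        assert len(subjects) == 24
        per_subject = pd.Series([t.subject_id for t in truth]).value_counts()
        lo, hi = CohortConfig().tasks_per_subject
        assert per_subject.between(lo, hi).all()
        assert (subjects["n_airways"] == per_subject[subjects["subject_id"]].to_numpy()).all()

    def test_seed_determinism(self):
        t1, s1 = generate_cohort(5, SMALL_COHORT)
        t2, s2 = generate_cohort(5, SMALL_COHORT)
        assert t1 == t2
        pd.testing.assert_frame_equal(s1, s2)

    def test_implied_wtr_always_in_half_open_interval(self):
        truth, _ = generate_cohort(11, CohortConfig(n_subjects=24, tasks_per_subject=(400, 420)))
        wtr = np.array([t.true_wtr for t in truth])
        assert len(wtr) >= 10_000 - 500  # ~24*410 draws
        assert np.all((wtr > 0) & (wtr < 0.5))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            CohortConfig(tasks_per_subject=(5, 2))


class TestWorkers:
    def test_behavior_mixture_respected_at_every_stratum(self):
        workers = generate_workers(3, CrowdConfig(n_workers=500))
        share = sum(w.behavior is Behavior.CAREFUL for w in workers) / 500
        assert share == pytest.approx(0.43, abs=0.01)
        # mixture is spread across productivity ranks, so the
        # productivity-weighted careful share stays close to the target too
        prod = np.array([w.productivity for w in workers])
        careful = np.array([w.behavior is Behavior.CAREFUL for w in workers])
        weighted = prod[careful].sum() / prod.sum()
        assert weighted == pytest.approx(0.43, abs=0.06)

    def test_heavy_tailed_productivity(self):
        workers = generate_workers(3, CrowdConfig(n_workers=577))
        prod = np.sort([w.productivity for w in workers])[::-1]
        # top 5% of workers carry several times their proportional share
        assert prod[:29].sum() / prod.sum() > 0.2

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            WorkerProfile("w", Behavior.CAREFUL, noise_scale=-0.1)
        with pytest.raises(ValueError):
            WorkerProfile("w", Behavior.CAREFUL, productivity=0.5)


def all_behavior_config(behavior, n_workers=40):
    return CrowdConfig(
        n_workers=n_workers,
        results_per_task=10,
        behavior_mixture={behavior: 1.0},
    )


class TestCrowd:
    def test_noiseless_careful_crowd_recovers_truth_exactly(self):
        truth, _ = generate_cohort(2, SMALL_COHORT)
        cfg = all_behavior_config(Behavior.CAREFUL)
        workers = [
            WorkerProfile(w.worker_id, w.behavior, noise_scale=0.0,
                          center_jitter=0.0, productivity=w.productivity)
            for w in generate_workers(4, cfg)
        ]
        results, _ = simulate_crowd(truth, workers, seed=6, results_per_task=10)
        labels = classify_results_table(results, PipelineConfig())
        assert (labels["status"] == "valid").all()
        frame = ImageFrame()
        by_task = {t.task_id: t for t in truth}
        for r in results:
            m = measure_result(r, frame)
            t = by_task[r.task_id]
            assert m.inner_area == pytest.approx(t.true_inner_area, rel=1e-9)
            assert m.outer_area == pytest.approx(t.true_outer_area, rel=1e-9)
            assert m.wtr == pytest.approx(t.true_wtr, rel=1e-9)

    def test_all_no_airway_population_fully_flagged(self):
        truth, _ = generate_cohort(2, SMALL_COHORT)
        # difficulty-independent check: force markers by setting difficulty 1
        truth = [
            type(t)(t.task_id, t.subject_id, t.true_inner_radius,
                    t.true_wall_thickness, t.eccentricity, 1.0)
            for t in truth
        ]
        workers = generate_workers(4, all_behavior_config(Behavior.NO_AIRWAY_PRONE))
        results, log = simulate_crowd(truth, workers, seed=6, results_per_task=10)
        labels = classify_results_table(results, PipelineConfig())
        markers = log["emitted_mode"] == Behavior.NO_AIRWAY_PRONE.value
        flagged = labels.set_index("result_id")["no_airway_flag"]
        assert flagged[log.loc[markers, "result_id"]].all()
        assert (labels["status"] == "invalid").all()

    def test_configured_mixture_reflected_in_validity_shares(self, sim_study, sim_labels):
        """Default mixture (43% careful): valid share within 3 points of 43%."""
        summary = tabulate_validity_from_frame(sim_labels)
        assert abs(summary.fraction("valid") - 0.43) <= 0.03
        # multi-pair exclusions come from the spam tail: a few percent
        assert 0.01 <= summary.fraction("multi_pair") <= 0.05

    def test_results_per_task_and_distinct_workers(self, sim_study):
        df = sim_study["log"]
        per_task = df.groupby("task_id")
        assert (per_task.size() == 20).all()
        assert (per_task["worker_id"].nunique() == 20).all()

    def test_determinism(self):
        truth, _ = generate_cohort(2, SMALL_COHORT)
        workers = generate_workers(4, CrowdConfig(n_workers=60, results_per_task=5))
        r1, log1 = simulate_crowd(truth, workers, seed=9, results_per_task=5)
        r2, log2 = simulate_crowd(truth, workers, seed=9, results_per_task=5)
        assert r1 == r2
        pd.testing.assert_frame_equal(log1, log2)

    def test_empty_worker_list_rejected(self):
        truth, _ = generate_cohort(2, SMALL_COHORT)
        with pytest.raises(ValueError):
            simulate_crowd(truth, [], seed=1)


class TestExperts:
    def test_zero_noise_experts_identical_to_truth(self):
        truth, _ = generate_cohort(3, SMALL_COHORT)
        refs = simulate_experts(truth, seed=1, expert_noise_scale=0.0)
        tbl = expert_measure_table(refs)
        e1 = tbl[tbl["expert_id"] == "1"].set_index("task_id")
        e2 = tbl[tbl["expert_id"] == "2"].set_index("task_id")
        for t in truth:
            assert e1.loc[t.task_id, "inner_area"] == pytest.approx(t.true_inner_area)
        assert pearson(e1["inner_area"], e2.loc[e1.index, "inner_area"]) == pytest.approx(1.0)

    def test_expert_agreement_decreases_with_noise(self):
        truth, _ = generate_cohort(3, CohortConfig(n_subjects=8, tasks_per_subject=(40, 50)))
        rhos = []
        for noise in (0.02, 0.10, 0.40):
            refs = simulate_experts(truth, seed=2, expert_noise_scale=noise)
            tbl = expert_measure_table(refs)
            e1 = tbl[tbl["expert_id"] == "1"].set_index("task_id")["inner_area"]
            e2 = tbl[tbl["expert_id"] == "2"].set_index("task_id")["inner_area"]
            rhos.append(pearson(e1, e2.loc[e1.index]))
        assert rhos[0] > rhos[1] > rhos[2]

    def test_areas_positive_and_ordered(self):
        truth, _ = generate_cohort(4, SMALL_COHORT)
        refs = simulate_experts(truth, seed=3, expert_noise_scale=0.5)
        for r in refs:
            assert 0 < r.inner_area < r.outer_area

    def test_bad_parameters_rejected(self):
        truth, _ = generate_cohort(4, SMALL_COHORT)
        with pytest.raises(ValueError):
            simulate_experts(truth, seed=1, expert_noise_scale=-0.1)
        with pytest.raises(ValueError):
            simulate_experts(truth, seed=1, n_experts=0)


class TestSimulateStudy:
    def test_master_seed_fully_determines_outputs(self):
        kw = dict(cohort_config=SMALL_COHORT,
                  crowd_config=CrowdConfig(n_workers=60, results_per_task=5))
        a = simulate_study(3, **kw)
        b = simulate_study(3, **kw)
        assert a["results"] == b["results"]
        pd.testing.assert_frame_equal(a["subjects"], b["subjects"])
        assert a["experts"] == b["experts"]
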