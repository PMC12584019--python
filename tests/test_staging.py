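"""Stepwise derivation, retention/merge rules and stage assignment."""

import numpy as np
import pytest

from clinstage import (
    Cohort,
    FunctionalStaging,
    PatientRecord,
    RetentionCriteria,
    SimulationParams,
    StagingError,
    assign_stage,
    run_stepwise,
    simulate_cohort,
    stage_distribution,
)
from clinstage.errors import ParameterError


def small_cohort(score_td_pairs):
    return Cohort(
        [
            PatientRecord(f"P{i}", s, td, 60.0, "male", "other")
            for i, (s, td) in enumerate(score_td_pairs)
        ]
    )


class TestTable2Fixture:
    def test_forced_steps_reproduce_published_cells(self, table2_results):
        steps = {r.upper_level: r for r in table2_results.audit if r.confusion}
        s1, s2 = steps[3], steps[2]
        assert (s1.confusion.tp, s1.confusion.fp, s1.confusion.tn, s1.confusion.fn) == (12, 93, 162, 3)
        assert (s2.confusion.tp, s2.confusion.fp, s2.confusion.tn, s2.confusion.fn) == (19, 63, 79, 4)

    def test_remaining_sample_recursion(self, table2_results):
        steps = {r.upper_level: r for r in table2_results.audit if r.confusion}
        assert steps[3].n_remaining == 270
        assert steps[2].n_remaining == 270 - (12 + 93) == 165

    def test_stage_distribution_83_82_105(self, table2_cohort, table2_results):
        dist = stage_distribution(table2_cohort, table2_results)
        d = dict(zip(dist["stage"], dist["count"]))
        assert d == {"light": 83, "moderate": 82, "high": 105}
        p = dict(zip(dist["stage"], dist["pct"]))
        assert p == {"light": 30.7, "moderate": 30.4, "high": 38.9}


class TestAssignStage:
    @pytest.mark.parametrize(
        "score, expected",
        [(192, "high"), (300, "high"), (191, "moderate"), (135, "moderate"),
         (134, "light"), (0, "light")],
    )
    def test_band_boundaries(self, table2_results, score, expected):
        assert assign_stage(score, table2_results) == expected

    def test_out_of_range_rejected(self, table2_results):
        with pytest.raises(StagingError):
            table2_results.assign_stage(301)

    def test_partition_completeness(self, table2_results):
        idx = table2_results.stage_index(np.arange(0, 301))
        assert set(np.unique(idx)) == {0, 1, 2}
        assert np.all(np.diff(idx) >= 0)  # stage index increases with score


class TestRecovery:
    def test_noise_free_planted_thresholds_recovered_exactly(self):
        c = simulate_cohort(
            SimulationParams(n=5000, td_thresholds=(120, 150, 200), td_noise=0.0, seed=7)
        )
        res = run_stepwise(c)
        assert res.cutoffs == (120, 150, 200)
        assert res.n_stages == 4

    def test_recovery_feeds_stage_assignment(self):
        c = simulate_cohort(
            SimulationParams(n=5000, td_thresholds=(120, 150, 200), td_noise=0.0, seed=7)
        )
        res = run_stepwise(c)
        # with no noise, assigned stage equals the generating TD level
        assert np.array_equal(res.stage_index(c.admission_scores), c.td_levels)


class TestDegenerateAndRules:
    def test_single_td3_patient_skipped_one_stage_model(self):
        pairs = [(50, 0)] * 10 + [(250, 3)]
        with pytest.warns(UserWarning, match="1-stage"):
            res = run_stepwise(small_cohort(pairs))
        assert res.cutoffs == ()
        assert res.n_stages == 1
        assert any("skipped" in w for w in res.warnings)
        # every patient still maps to the single stage
        assert res.stage_distribution()["count"].sum() == 11

    def test_fewer_than_two_levels_is_error(self):
        with pytest.raises(StagingError, match="2 distinct TD levels"):
            run_stepwise(small_cohort([(10, 1), (20, 1)]))

    def test_low_auc_candidate_dropped(self):
        # scores carry no information about TD: AUC ~ 0.5 -> dropped
        rng = np.random.default_rng(0)
        pairs = [(int(s), int(td)) for s, td in zip(rng.integers(0, 301, 400), rng.integers(0, 2, 400))]
        with pytest.warns(UserWarning):
            res = run_stepwise(small_cohort(pairs))
        assert res.cutoffs == ()
        dropped = [r for r in res.audit if r.metrics and not r.retained]
        assert dropped and all("dropped" in r.reason for r in dropped)

    def test_merge_rule_drops_lower_youden(self):
        # plant two thresholds 8 points apart; the weaker one must go
        c = simulate_cohort(
            SimulationParams(n=4000, td_thresholds=(140, 148, 240), td_noise=0.0, seed=2)
        )
        res = run_stepwise(c, criteria=RetentionCriteria(min_separation=15))
        assert len(res.cutoffs) == 2
        assert 240 in res.cutoffs
        assert sum(c in (140, 148) for c in res.cutoffs) == 1
        merged = [r for r in res.audit if "merged" in r.reason]
        assert len(merged) == 1

    def test_retained_cutoffs_respect_separation(self):
        for seed in range(5):
            c = simulate_cohort(SimulationParams(n=800, seed=seed))
            res = run_stepwise(c)
            gaps = np.diff(res.cutoffs)
            assert np.all(gaps >= res.criteria.min_separation)

    def test_forced_cutoff_flagged_in_audit(self, table2_results):
        assert all(r.forced for r in table2_results.audit if r.metrics)
        assert any("forced" in r.reason for r in table2_results.audit)

    def test_criteria_validation(self):
        with pytest.raises(ParameterError):
            RetentionCriteria(min_auc=0.4)
        with pytest.raises(ParameterError):
            RetentionCriteria(min_youden=1.5)
        with pytest.raises(ParameterError):
            RetentionCriteria(min_separation=-1)


class TestResultsSurface:
    def test_summary_contains_published_row(self, table2_results):
        s = table2_results.summary()
        assert "192" in s and "0.800" in s and "0.635" in s
        assert "high vs moderate" in s

    def test_to_dict_roundtrips_cells(self, table2_results):
        d = table2_results.to_dict()
        row = next(s for s in d["steps"] if s.get("cutoff") == 192)
        assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (12, 93, 162, 3)
        assert row["youden"] == 0.435
        assert d["cutoffs"] == [135, 192]

    def test_model_from_cohort_equivalent(self, table2_cohort):
        direct = FunctionalStaging(
            table2_cohort.admission_scores, table2_cohort.td_levels
        ).fit(forced_cutoffs={3: 192, 2: 135})
        assert direct.cutoffs == (135, 192)


def test_plot_stages_renders_band_per_stage(table2_results):
    import matplotlib

    matplotlib.use("Agg")
    ax = table2_results.plot_stages()
    assert ax.get_xlim() == (0.0, 301.0)
    assert len(ax.texts) == table2_results.n_stages
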