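"""Scenario runs, spiral detection and summary statistics.

These tests exercise the compiled batch engine at reduced problem sizes
and pin it to closed-form limits and to the object-level reference
implementation's invariants.
"""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from labaudit import (
    AuditPolicy,
    ScenarioConfig,
    WorldParams,
    detect_spiral,
    false_positive_prob,
    fp_per_100_papers,
    mistakes_per_100_papers,
    nonparametric_ci,
    run_batch,
    run_scenario,
    run_simulation,
    sensitivity_grid,
    summarize_batch,
    sensitivity_scenarios,
)
from labaudit.experiments import batch_records_frame


def small_config(**kwargs):
    defaults = dict(total_cycles=4_000, record_every=400, n_replicates=3, master_seed=11)
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="module")
def audited_run():
    """One small audited batch, reused across structural tests."""
    cfg = small_config(audit=AuditPolicy(cycles_per_audit=50))
    return cfg, run_batch(cfg, collect_audits=True)


class TestRunSimulation:
    def test_single_record_when_cycles_equal_record_every(self):
        cfg = small_config(total_cycles=800, record_every=800, n_replicates=1)
        frame = run_simulation(cfg)
        assert len(frame) == 1
        assert frame["cycle"].iloc[0] == 800

    def test_record_count_and_schema(self, audited_run):
        cfg, result = audited_run
        frame = batch_records_frame(result)
        assert len(frame) == cfg.n_replicates * cfg.total_cycles // cfg.record_every
        assert list(frame.columns) == [
            "replicate", "cycle", "mean_effort", "mean_alpha", "cum_papers",
            "cum_fps", "cum_mistakes", "cum_audits", "cum_removals", "cum_cost",
        ]

    def test_closed_form_limit_without_mutation_or_audits(self):
        cfg = small_config(world=WorldParams(mutation_prob=0.0),
                           audit=AuditPolicy(enabled=False))
        result = run_batch(cfg)
        expected = false_positive_prob(cfg.world.power, cfg.world.initial_effort)
        assert np.allclose(result.mean_alpha, expected, atol=1e-12)
        assert np.allclose(result.mean_effort, cfg.world.initial_effort)

    def test_engine_rates_match_closed_form_composition(self):
        """The compiled engine reproduces the analytic per-cycle rates:
        papers at 0.625 per lab-cycle and false positives at 0.045 per
        paper when every lab sits at e=75."""
        cfg = small_config(world=WorldParams(mutation_prob=0.0),
                           audit=AuditPolicy(enabled=False),
                           total_cycles=8_000, record_every=8_000, n_replicates=3)
        result = run_batch(cfg)
        lab_cycles = 100 * cfg.total_cycles
        paper_rate = result.final_papers / lab_cycles
        assert np.allclose(paper_rate, 0.625, atol=0.005)
        fp_rate = result.final_false_positives / result.final_papers
        assert np.allclose(fp_rate, 0.045, atol=0.004)
        mistake_share = result.final_mistakes / result.final_false_positives
        assert np.allclose(mistake_share, 0.25, atol=0.04)

    def test_bit_identical_under_same_seed(self, audited_run):
        cfg, result = audited_run
        again = run_batch(cfg)
        assert np.array_equal(result.mean_alpha, again.mean_alpha)
        assert np.array_equal(result.cum_audit_cost, again.cum_audit_cost)
        assert np.array_equal(result.cum_papers, again.cum_papers)

    def test_batch_row_equals_single_replicate_run(self, audited_run):
        """A replicate's trajectory depends only on its own derived seed,
        so running it alone reproduces its batch row bit for bit."""
        cfg, result = audited_run
        frame = batch_records_frame(result)
        for rep in range(cfg.n_replicates):
            alone = run_simulation(cfg, replicate=rep)
            row = frame[frame["replicate"] == rep].reset_index(drop=True)
            pd.testing.assert_frame_equal(alone, row)

    def test_zero_review_error_matches_baseline_stream(self, audited_run):
        cfg, result = audited_run
        explicit = dataclasses.replace(
            cfg, audit=dataclasses.replace(cfg.audit, review_error_pct=0.0))
        again = run_batch(explicit)
        assert np.array_equal(result.mean_alpha, again.mean_alpha)

    def test_replicate_index_out_of_range(self):
        with pytest.raises(ValueError):
            run_simulation(small_config(), replicate=99)


class TestEngineInvariants:
    def test_cumulative_fields_monotone_and_ordered(self, audited_run):
        _, result = audited_run
        for arr in (result.cum_papers, result.cum_false_positives,
                    result.cum_mistakes, result.cum_audits, result.cum_removals,
                    result.cum_audit_cost, result.cum_audited_papers):
            assert np.all(np.diff(arr, axis=0) >= 0)
        assert np.all(result.cum_false_positives <= result.cum_papers)
        assert np.all(result.cum_mistakes <= result.cum_false_positives)
        assert np.all(result.cum_removals <= result.cum_audits)

    def test_no_lab_audited_twice(self, audited_run):
        _, result = audited_run
        assert result.audit_log, "expected audits in this configuration"
        for rep in set(a["replicate"] for a in result.audit_log):
            uids = [a["lab_uid"] for a in result.audit_log if a["replicate"] == rep]
            assert len(uids) == len(set(uids))

    def test_audited_labs_meet_eligibility_and_cutoff_floor(self, audited_run):
        cfg, result = audited_run
        for a in result.audit_log:
            assert a["papers"] >= cfg.audit.min_papers
            assert 0.0 <= a["statistic_true"] <= 1.0
            assert a["cutoff"] >= cfg.audit.resolved_floor

    def test_audit_cost_accounting_matches_cost_model(self, audited_run):
        cfg, result = audited_run
        per_rep = {}
        for a in result.audit_log:
            per_rep.setdefault(a["replicate"], 0.0)
            per_rep[a["replicate"]] += a["cost"]
            assert a["cost"] == pytest.approx(a["papers"] * 8_750.0)
        for rep, total in per_rep.items():
            assert result.cum_audit_cost[-1, rep] == pytest.approx(total)

    def test_removal_disabled_at_percentile_one(self):
        cfg = small_config(audit=AuditPolicy(cycles_per_audit=50, cutoff_percentile=1.0))
        result = run_batch(cfg)
        assert np.all(result.cum_removals == 0)
        assert np.all(result.cum_audits[-1] > 0)


class TestSpiralDetection:
    def test_low_alpha_trajectory_is_not_a_spiral(self):
        assert not detect_spiral([0.05] * 100)

    def test_trajectory_ending_at_maximum_is_a_spiral(self):
        assert detect_spiral([0.05] * 99 + [2 / 3])

    def test_boundary_is_inclusive(self):
        assert detect_spiral([0.05, 0.6], threshold=0.6)

    def test_accepts_records_frame(self):
        frame = pd.DataFrame({"mean_alpha": [0.05, 0.65]})
        assert detect_spiral(frame)

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError):
            detect_spiral([])


class TestRates:
    def test_fp_and_mistake_rates(self):
        assert fp_per_100_papers(0, 5000) == 0.0
        assert fp_per_100_papers(1510, 5000) == pytest.approx(30.2)
        assert mistakes_per_100_papers(405, 5000) == pytest.approx(8.1)

    def test_zero_papers_raise(self):
        with pytest.raises(ValueError):
            fp_per_100_papers(1, 0)


class TestNonparametricCI:
    def test_constant_sample_degenerates(self):
        assert nonparametric_ci([3.5] * 40) == (3.5, 3.5)

    def test_matches_sorted_oracle_on_1_to_100(self):
        sample = list(range(1, 101))
        lo, hi = nonparametric_ci(sample)
        ordered = sorted(sample)
        import math
        assert lo == ordered[math.ceil(0.025 * 100) - 1]
        assert hi == ordered[math.ceil(0.975 * 100) - 1]

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=80))
    def test_contains_median_and_is_ordered(self, sample):
        lo, hi = nonparametric_ci(sample)
        assert lo <= np.median(sample) <= hi

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            nonparametric_ci([])


class TestScenarioSummaries:
    def test_single_replicate_summary_is_degenerate(self):
        cfg = small_config(n_replicates=1, audit=AuditPolicy(cycles_per_audit=50))
        summary, result = run_scenario(cfg, return_result=True)
        assert summary.pct_avoiding_spiral in (0.0, 100.0)
        lo, hi = summary.fp_per_100_papers_ci
        assert lo == pytest.approx(summary.fp_per_100_papers)
        assert hi == pytest.approx(summary.fp_per_100_papers)
        assert summary.pct_papers_audited == pytest.approx(
            100.0 * result.cum_audited_papers[-1, 0] / result.cum_papers[-1, 0])

    def test_same_master_seed_gives_identical_summary(self):
        cfg = small_config(audit=AuditPolicy(cycles_per_audit=50))
        assert run_scenario(cfg) == run_scenario(cfg)

    def test_ci_bounds_are_ordered_and_bracket_means_plausibly(self, audited_run):
        cfg, result = audited_run
        summary = summarize_batch(result, cfg)
        for lo_hi in (summary.pct_papers_audited_ci, summary.cost_per_paper_ci,
                      summary.fp_per_100_papers_ci, summary.mistakes_per_100_papers_ci):
            assert lo_hi[0] <= lo_hi[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(total_cycles=1000, record_every=300)
        with pytest.raises(ValueError):
            ScenarioConfig(n_replicates=0)


class TestSensitivityGrid:
    def test_sixteen_scenarios_with_expected_settings(self):
        configs = sensitivity_scenarios(n_replicates=2, total_cycles=800, record_every=400)
        assert len(configs) == 16
        labels = [c.label for c in configs]
        assert len(set(labels)) == 16
        by_label = {c.label: c for c in configs}
        assert not by_label["no_audits"].audit.enabled
        assert by_label["j50_baseline"].audit.cycles_per_audit == 50
        assert by_label["j200_mistake_audits"].audit.statistic == "mistake_proportion"
        assert by_label["j200_mistake_audits"].audit.effort_boost_network == 0.5
        assert by_label["j75_e0_10"].world.initial_effort == 10.0
        assert by_label["j75_n25"].audit.min_papers == 25
        assert by_label["j75_review_error20"].audit.review_error_pct == 20.0
        assert by_label["j75_no_removal"].audit.cutoff_percentile == 1.0

    def test_grid_runner_tabulates_and_sorts(self):
        configs = sensitivity_scenarios(n_replicates=2, total_cycles=800, record_every=400)[:3]
        frame = sensitivity_grid(configs)
        assert len(frame) == 3
        assert frame["pct_avoiding_spiral"].is_monotonic_decreasing
        assert {"label", "pct_avoiding_spiral", "fp_per_100_papers"} <= set(frame.columns)
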