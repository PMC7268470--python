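import numpy as np
import pandas as pd
import pytest

from colddeck import (
    StudyConfig,
    run_calibration,
    run_simulation_study,
    run_study,
    summarize,
    validate_pairs_study,
)

CFG100 = StudyConfig(behaviours=("b",), repetitions=100, seed=1)


def _by(result, estimand, target=None, behaviour=None, subgroup="overall"):
    out = [
        s
        for s in result.summaries
        if s.estimand == estimand
        and s.subgroup == subgroup
        and (target is None or s.target_rr == target)
        and (behaviour is None or s.behaviour == behaviour)
    ]
    assert len(out) == 1, f"{estimand}/{target}: {len(out)} rows"
    return out[0]


class TestSummarize:
    def test_median_and_percentiles_of_1_to_100(self):
        s = summarize(np.arange(1.0, 101.0), estimand="rr_i", config=CFG100)
        assert s.median == pytest.approx(50.5)
        # (n+1)q plotting position: 2.5th pct between 2nd and 3rd order stats
        assert s.lower == pytest.approx(2.525)
        assert s.upper == pytest.approx(98.475)

    def test_failed_rule_strictly_greater_than_5_percent(self):
        values = np.ones(100)
        imp = np.zeros(100, dtype=bool)
        imp[:6] = True
        assert summarize(values, imp, estimand="rr_t", config=CFG100).failed
        imp[:] = False
        imp[:5] = True
        assert not summarize(values, imp, estimand="rr_t", config=CFG100).failed

    def test_failed_rule_only_for_corrected_estimands(self):
        values = np.ones(100)
        imp = np.ones(100, dtype=bool)
        assert not summarize(values, imp, estimand="rr_i", config=CFG100).failed

    def test_impossible_and_invalid_excluded_from_percentiles(self):
        values = np.array([1.0, 2.0, 3.0, -5.0, float("nan")])
        imp = np.array([False, False, False, True, False])
        inv = np.array([False, False, False, False, True])
        s = summarize(values, imp, inv, estimand="rr_t",
                      config=CFG100.replace(repetitions=5))
        assert s.median == pytest.approx(2.0)
        assert s.impossible_count == 1 and s.invalid_count == 1

    def test_single_repetition_degenerate_interval(self):
        s = summarize([1.7], estimand="rr_i", config=CFG100.replace(repetitions=1))
        assert s.median == s.lower == s.upper == pytest.approx(1.7)

    def test_zero_valid_draws_sentinel(self):
        s = summarize(
            [float("nan")], invalid=[True], estimand="rr_i",
            config=CFG100.replace(repetitions=1),
        )
        assert np.isnan(s.median)


class TestRunStudy:
    def test_summaries_cover_all_estimands(self, recipients, donors, config):
        result = run_study(recipients, donors, config)
        estimands = {(s.behaviour, s.estimand) for s in result.summaries}
        for b in config.behaviours:
            for e in ("p_hat", "rho_hat", "excess_matches", "rr_i",
                      "adj_rr_i", "rr_t", "adj_rr_t"):
                assert (b, e) in estimands

    def test_determinism_same_seed_identical_summaries(self, recipients, donors,
                                                       config):
        r1 = run_study(recipients, donors, config)
        r2 = run_study(recipients, donors, config)
        assert len(r1.summaries) == len(r2.summaries)
        for a, b in zip(r1.summaries, r2.summaries):
            assert a == b
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_different_seed_changes_draws(self, recipients, donors, config):
        r1 = run_study(recipients, donors, config)
        r2 = run_study(recipients, donors, config.replace(seed=99))
        assert not r1.draws["value"].equals(r2.draws["value"])

    def test_subgroup_rows_present(self, recipients, donors, config):
        recipients = recipients.copy()
        recipients["subgroup"] = np.where(
            np.arange(len(recipients)) % 2 == 0, "escc", "eac"
        )
        result = run_study(recipients, donors, config)
        subgroups = {s.subgroup for s in result.summaries}
        assert {"overall", "escc", "eac"} <= subgroups

    def test_calibration_only_study_needs_no_outcome(self, recipients, donors,
                                                     config):
        recipients = recipients.copy()
        recipients["death_within_1yr"] = pd.NA
        result = run_calibration(recipients, donors, config)
        assert _by(result, "p_hat", behaviour="smoking").n == len(recipients)


class TestSimulationStudy:
    def test_pairs_study_null_target_recovers_one(self):
        cfg = StudyConfig(behaviours=("b",), repetitions=50, seed=3)
        result = validate_pairs_study("b", 27_835, 0.159, 0.071, cfg,
                                      targets=(1.0,), death_rate=0.54)
        assert _by(result, "rr_sim", 1.0).median == pytest.approx(1.0, abs=0.01)
        assert _by(result, "rr_t", 1.0).median == pytest.approx(1.0, abs=0.25)

    def test_infeasible_target_reported_not_possible(self):
        cfg = StudyConfig(behaviours=("b",), repetitions=5, seed=3)
        result = validate_pairs_study("b", 10_000, 0.048, 0.011, cfg,
                                      targets=(1.0, 2.0), death_rate=0.54)
        row = _by(result, "rr_t", 2.0)
        assert row.not_possible
        assert _by(result, "rr_t", 1.0).not_possible is False
        # purged draws: nothing recorded at the infeasible target
        assert not (result.draws["target_rr"] == 2.0).any()

    def test_full_simulation_study_runs_on_tables(self, recipients, donors,
                                                  config):
        cfg = config.replace(repetitions=2)
        result = run_simulation_study(recipients, donors, cfg, targets=(1.0,),
                                      death_rate=0.5)
        estimands = {s.estimand for s in result.summaries}
        assert {"rr_sim", "rr_i", "rr_t"} <= estimands

    def test_simulated_rr_tracks_target_grid(self):
        cfg = StudyConfig(behaviours=("b",), repetitions=30, seed=5)
        result = validate_pairs_study("b", 27_835, 0.159, 0.071, cfg,
                                      targets=(0.8, 1.25), death_rate=0.54)
        for target in (0.8, 1.25):
            assert _by(result, "rr_sim", target).median == pytest.approx(
                target, abs=0.02
            )

    def test_pairs_study_deterministic(self):
        cfg = StudyConfig(behaviours=("b",), repetitions=10, seed=8)
        r1 = validate_pairs_study("b", 5_000, 0.2, 0.05, cfg, targets=(1.5,))
        r2 = validate_pairs_study("b", 5_000, 0.2, 0.05, cfg, targets=(1.5,))
        assert r1.summaries == r2.summaries
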