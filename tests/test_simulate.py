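"""Tests for the generative simulator of the two-group experiment."""

import numpy as np
import pandas as pd
import pytest

from srcmon.behavioral import goodman_kruskal_gamma
from srcmon.mpt import MPTDomainError, MPTParameters, category_probabilities
from srcmon.simulate import (
    ExperimentConfig,
    aggregate_frequencies,
    calibrate_2afc,
    simulate_experiment,
    validate_dataset,
)

SMALL = ExperimentConfig(n_participants=8)


class TestConfig:
    def test_2afc_defaults_solve_reference_accuracies(self):
        cfg = ExperimentConfig()
        p_exp = cfg.afc_retrieval_expected + (
            1 - cfg.afc_retrieval_expected
        ) * cfg.afc_guessing
        p_unexp = cfg.afc_retrieval_unexpected + (
            1 - cfg.afc_retrieval_unexpected
        ) * (1 - cfg.afc_guessing)
        assert p_exp == pytest.approx(1732 / 2304, abs=1e-12)
        assert p_unexp == pytest.approx(1406 / 2304, abs=1e-12)

    def test_calibrate_2afc_closed_form(self):
        a_e, a_u, g2 = calibrate_2afc(0.752, 0.572, 0.20)
        assert a_e + (1 - a_e) * g2 == pytest.approx(0.752)
        assert a_u + (1 - a_u) * (1 - g2) == pytest.approx(0.572)

    def test_cap_larger_than_item_pool_rejected(self):
        with pytest.raises(MPTDomainError, match="restudy cap"):
            ExperimentConfig(n_items_per_type=8, restudy_cap=32)


class TestSimulateExperiment:
    def test_bit_identical_under_seed(self):
        a = simulate_experiment(SMALL, seed=3)
        b = simulate_experiment(SMALL, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_full_scale_test_phase_counts(self, full_scale_trials):
        test = full_scale_trials[full_scale_trials["phase"] == "test"]
        counts = test.groupby(["group", "expectancy"]).size()
        assert set(counts) == {2304}

    def test_restudy_cap_enforced_everywhere(self, full_scale_trials):
        chosen = (
            full_scale_trials[full_scale_trials["restudy_choice"] == 1.0]
            .groupby("participant")
            .size()
        )
        assert chosen.max() <= 32
        restudied = (
            full_scale_trials[full_scale_trials["phase"] == "restudy"]
            .groupby("participant")
            .size()
        )
        assert set(restudied) == {32}

    def test_jos_only_in_judgment_phases(self, full_scale_trials):
        with_jos = full_scale_trials[full_scale_trials["jos"].notna()]
        imm = with_jos[with_jos["group"] == "immediate"]
        del_ = with_jos[with_jos["group"] == "delayed"]
        assert set(imm["phase"]) == {"study"}
        assert set(del_["phase"]) == {"delayed_judgment"}

    def test_new_items_only_at_test(self, full_scale_trials):
        new = full_scale_trials[full_scale_trials["expectancy"] == "new"]
        assert set(new["phase"]) == {"test"}

    def test_degenerate_chooser_gets_fifty_fifty_substitution(self):
        # choice probability ~0 for every JOS: nothing chosen, substitution
        # must fill exactly 16 expected + 16 unexpected pairs
        cfg = ExperimentConfig(n_participants=4, choice_midpoint=-1e9)
        trials = simulate_experiment(cfg, seed=0)
        restudy = trials[trials["phase"] == "restudy"]
        per_cell = restudy.groupby(["participant", "expectancy"]).size().unstack()
        assert (per_cell["expected"] == 16).all()
        assert (per_cell["unexpected"] == 16).all()

    def test_large_sample_proportions_match_tree_probabilities(self):
        cfg = ExperimentConfig(n_participants=250, heterogeneity_sd=0.0)
        trials = simulate_experiment(cfg, seed=9)
        agg = aggregate_frequencies(trials)
        for group in ("immediate", "delayed"):
            params = MPTParameters.from_free(
                [cfg.group_means[group][k]
                 for k in ("D_E", "D_U", "d_E", "d_U", "b", "g")]
            )
            P = category_probabilities(params).probs
            counts = agg.group_3afc[group].counts
            n = counts.sum(axis=1, keepdims=True)
            se = np.sqrt(P * (1 - P) / n)
            assert np.all(np.abs(counts / n - P) <= 4 * se + 1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_qualitative_fidelity_at_defaults(self, seed):
        cfg = ExperimentConfig(n_participants=24)
        trials = simulate_experiment(cfg, seed=seed)
        judged = trials[trials["jos"].notna()]
        cells = judged.groupby(["group", "expectancy"])["jos"].mean().unstack()
        imm_diff = cells.loc["immediate", "expected"] - cells.loc[
            "immediate", "unexpected"]
        del_diff = cells.loc["delayed", "expected"] - cells.loc[
            "delayed", "unexpected"]
        assert imm_diff > 2.0          # expectancy effect on immediate JOSs
        assert abs(del_diff) < 4.0     # near-null on delayed JOSs
        # participant-level gammas predominantly negative
        chosen = judged[judged["restudy_choice"].notna()]
        gammas = []
        for _, sub in chosen.groupby(["group", "participant"]):
            r = goodman_kruskal_gamma(
                sub["jos"].astype(float), sub["restudy_choice"].astype(float)
            )
            if r.defined:
                gammas.append(r.gamma)
        assert np.mean(np.array(gammas) < 0) > 0.8


class TestAggregateFrequencies:
    def test_conservation_per_group(self):
        trials = simulate_experiment(SMALL, seed=1)
        agg = aggregate_frequencies(trials)
        for table in agg.group_3afc.values():
            assert table.total == 8 * 96
        for tables in agg.participant_3afc.values():
            assert len(tables) == 8
            assert all(t.total == 96 for t in tables)

    def test_2afc_row_totals(self, full_scale_trials):
        agg = aggregate_frequencies(full_scale_trials)
        assert np.all(agg.group_2afc["delayed"].row_totals == 2304)

    def test_hand_built_fixture_matches_hand_tally(self):
        rows = []
        for pid, resp_exp, resp_unexp, resp_new in [
            ("p1", ["expected", "unexpected"], ["unexpected"], ["new", "expected"]),
            ("p2", ["expected"], ["expected", "new"], ["new"]),
        ]:
            for r in resp_exp:
                rows.append((pid, "g", "test", "i", "kitchen", "expected", r))
            for r in resp_unexp:
                rows.append((pid, "g", "test", "i", "bathroom", "unexpected", r))
            for r in resp_new:
                rows.append((pid, "g", "test", "i", "none", "new", r))
        trials = pd.DataFrame(
            rows,
            columns=["participant", "group", "phase", "item", "source",
                     "expectancy", "response"],
        )
        trials["jos"] = np.nan
        trials["restudy_choice"] = np.nan
        trials["restudied"] = np.nan
        agg = aggregate_frequencies(trials)
        expected_counts = np.array([[2, 1, 0], [1, 1, 1], [1, 0, 2]])
        assert np.array_equal(agg.group_3afc["g"].counts, expected_counts)

    def test_unknown_phase_rejected(self):
        trials = simulate_experiment(SMALL, seed=0).copy()
        trials.loc[trials.index[0], "phase"] = "warmup"
        with pytest.raises(MPTDomainError, match="unknown phase"):
            aggregate_frequencies(trials)


class TestValidateDataset:
    def test_zero_chooser_flagged(self):
        cfg = ExperimentConfig(n_participants=3, choice_midpoint=-1e9)
        trials = simulate_experiment(cfg, seed=0)
        report = validate_dataset(trials)
        reasons = {r for _, r in report.exclusions}
        assert "no restudy choices" in reasons
        assert len(report.flagged_ids) == 6  # all participants, both groups

    def test_all_yes_chooser_has_undefined_gamma(self):
        cfg = ExperimentConfig(n_participants=3, choice_midpoint=1e9)
        trials = simulate_experiment(cfg, seed=0)
        report = validate_dataset(trials)
        assert any("undefined gamma" in r for _, r in report.exclusions)

    def test_default_simulation_yields_empty_report(self):
        trials = simulate_experiment(ExperimentConfig(n_participants=10), seed=5)
        report = validate_dataset(trials)
        assert report.exclusions == ()
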