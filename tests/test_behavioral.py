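"""Tests for the behavioral statistics layer against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srcmon.behavioral import (
    StatsDomainError,
    anova_2x2,
    gamma_group_test,
    goodman_kruskal_gamma,
    independent_t,
    loftus_masson_ci,
    paired_t,
    paired_t_power,
    required_n_paired_t,
    restudy_rates_by_cell,
)


def _proj_ss(X: np.ndarray, y: np.ndarray) -> float:
    """Squared norm of the projection of y onto the column space of X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((X @ beta) ** 2))


def _dummies(labels) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels[:, None] == np.unique(labels)[None, :]).astype(float)


def mixed_anova_projection_oracle(df, dv, subject, between, within):
    """Sequential projection-matrix decomposition of the mixed 2x2 design."""
    y = df[dv].to_numpy(float)
    S = _dummies(df[subject])
    G = _dummies(df[between])
    W = _dummies(df[within])
    GW = _dummies(df[between].astype(str) + "/" + df[within].astype(str))
    one = np.ones((len(y), 1))
    ss_1 = _proj_ss(one, y)
    ss_g = _proj_ss(G, y) - ss_1
    ss_subj_err = _proj_ss(S, y) - _proj_ss(G, y)
    ss_w = _proj_ss(np.hstack([one, W]), y) - ss_1
    ss_gw = _proj_ss(GW, y) - ss_1 - ss_g - ss_w
    SW = np.hstack([S, GW])
    ss_w_err = float(y @ y) - _proj_ss(SW, y)
    return {"between": ss_g, "subj_err": ss_subj_err, "within": ss_w,
            "interaction": ss_gw, "within_err": ss_w_err}


def _mixed_frame(rng, n_per_group=6):
    rows = []
    for g, group in enumerate(("immediate", "delayed")):
        for i in range(n_per_group):
            pid = f"{group}{i}"
            for c, cond in enumerate(("expected", "unexpected")):
                y = rng.normal(50 + 3 * g - 4 * c + (5 if g == 0 and c == 0 else 0), 6)
                rows.append(dict(participant=pid, group=group, cond=cond, y=y))
    return pd.DataFrame(rows)


class TestAnova2x2Mixed:
    def test_null_data_gives_zero_f_and_eta(self):
        rows = [
            dict(participant=f"p{i}{g}", group=g, cond=c, y=7.0)
            for g in ("a", "b") for i in range(4) for c in ("x", "z")
        ]
        table = anova_2x2(pd.DataFrame(rows), dv="y", within="cond",
                          subject="participant", between="group")
        for e in table.effects:
            assert e.f == 0.0
            assert e.partial_eta_sq == 0.0

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(4)
        df = _mixed_frame(rng)
        table = anova_2x2(df, dv="y", within="cond", subject="participant",
                          between="group")
        oracle = mixed_anova_projection_oracle(df, "y", "participant", "group",
                                               "cond")
        assert table["group"].ss == pytest.approx(oracle["between"], rel=1e-9)
        assert table["cond"].ss == pytest.approx(oracle["within"], rel=1e-9)
        assert table["group * cond"].ss == pytest.approx(
            oracle["interaction"], rel=1e-9
        )
        n_err = oracle["within_err"] / table["cond"].df2
        assert table["cond"].ms_error == pytest.approx(n_err, rel=1e-9)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = _mixed_frame(rng, n_per_group=8)
        ours = anova_2x2(df, dv="y", within="cond", subject="participant",
                         between="group")
        theirs = pg.mixed_anova(data=df, dv="y", within="cond",
                                between="group", subject="participant")
        by_src = theirs.set_index("Source")
        assert ours["group"].f == pytest.approx(by_src.loc["group", "F"], rel=1e-9)
        assert ours["cond"].f == pytest.approx(by_src.loc["cond", "F"], rel=1e-9)
        assert ours["group * cond"].f == pytest.approx(
            by_src.loc["Interaction", "F"], rel=1e-9
        )
        assert ours["group"].partial_eta_sq == pytest.approx(
            by_src.loc["group", "np2"], rel=1e-9
        )
        assert ours["cond"].partial_eta_sq == pytest.approx(
            by_src.loc["cond", "np2"], rel=1e-9
        )

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(12)
        df = _mixed_frame(rng, n_per_group=10)
        y = df["y"].to_numpy()
        oracle = mixed_anova_projection_oracle(df, "y", "participant", "group",
                                               "cond")
        ss_total = float(np.sum((y - y.mean()) ** 2))
        assert sum(oracle.values()) == pytest.approx(ss_total, abs=1e-8)

    def test_unbalanced_groups_rejected(self):
        rng = np.random.default_rng(0)
        df = _mixed_frame(rng)
        df = df[df["participant"] != "immediate0"]
        with pytest.raises(StatsDomainError, match="balanced"):
            anova_2x2(df, dv="y", within="cond", subject="participant",
                      between="group")


class TestAnova2x2Within:
    @staticmethod
    def _frame(rng, n=8):
        rows = []
        for i in range(n):
            base = rng.normal(0, 3)
            for a in ("correct", "incorrect"):
                for b in ("expected", "unexpected"):
                    y = rng.normal(50 + base + (6 if a == "correct" else 0)
                                   + (2 if b == "expected" else 0), 4)
                    rows.append(dict(participant=i, acc=a, attr=b, y=y))
        return pd.DataFrame(rows)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = self._frame(rng)
        ours = anova_2x2(df, dv="y", within="acc", within2="attr",
                         subject="participant")
        theirs = pg.rm_anova(data=df, dv="y", within=["acc", "attr"],
                             subject="participant").set_index("Source")
        assert ours["acc"].f == pytest.approx(theirs.loc["acc", "F"], rel=1e-9)
        assert ours["attr"].f == pytest.approx(theirs.loc["attr", "F"], rel=1e-9)
        assert ours["acc * attr"].f == pytest.approx(
            theirs.loc["acc * attr", "F"], rel=1e-9
        )
        assert ours["acc"].p == pytest.approx(theirs.loc["acc", "p_unc"], rel=1e-9)

    def test_effect_specific_error_terms_df(self):
        rng = np.random.default_rng(8)
        df = self._frame(rng, n=12)
        table = anova_2x2(df, dv="y", within="acc", within2="attr",
                          subject="participant")
        assert all(e.df2 == 11 for e in table.effects)


class TestTTests:
    def test_identical_samples_give_zero(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.effect_size == 0.0 and r.zero_variance

    def test_hand_arithmetic_differences(self):
        # differences 1,2,3,4: mean 2.5, sd 1.29099; d_z = 1.93649
        r = paired_t([2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0, 4.0])
        assert r.effect_size == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))
        assert r.t == pytest.approx(r.effect_size * 2.0)
        assert r.df == 3

    @pytest.mark.parametrize(
        "t_value, expected_dz",
        [(12.23, 1.44), (1.88, 0.22), (13.07, 1.54), (4.37, 0.52), (6.33, 0.75)],
    )
    def test_dz_is_t_over_sqrt_n_at_n72(self, t_value, expected_dz):
        assert round(t_value / np.sqrt(72), 2) == expected_dz

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30),
        st.integers(0, 10_000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_dz_t_consistency_property(self, xs, seed):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = x + rng.normal(0, 3, x.size)
        if np.std(x - y, ddof=1) == 0:
            return
        r = paired_t(x, y)
        assert abs(r.effect_size - r.t / np.sqrt(len(xs))) < 1e-9

    def test_independent_t_pooled_df(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 71), rng.normal(0.4, 1, 72)
        r = independent_t(a, b)
        assert r.df == 141
        from scipy import stats

        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(t_ref, rel=1e-12)
        assert r.p == pytest.approx(p_ref, rel=1e-12)


class TestGamma:
    def test_perfect_negative_monotonicity(self):
        r = goodman_kruskal_gamma([10, 20, 30, 40], [1, 1, 0, 0])
        assert (r.concordant, r.discordant, r.gamma) == (0, 4, -1.0)

    def test_hand_enumerated_mixed_pattern(self):
        r = goodman_kruskal_gamma([10, 20, 30, 40], [1, 0, 1, 0])
        assert (r.concordant, r.discordant) == (1, 3)
        assert r.gamma == pytest.approx(-0.5)

    def test_constant_choices_undefined(self):
        r = goodman_kruskal_gamma([10, 20, 30], [0, 0, 0])
        assert not r.defined and r.gamma is None

    def test_exhaustive_patterns_match_brute_force(self):
        scores = [5, 12, 18, 33, 47, 80]
        for pattern in itertools.product([0, 1], repeat=6):
            r = goodman_kruskal_gamma(scores, list(pattern))
            C = D = 0
            for i in range(6):
                for j in range(i + 1, 6):
                    prod = (scores[i] - scores[j]) * (pattern[i] - pattern[j])
                    C += prod > 0
                    D += prod < 0
            if C + D == 0:
                assert not r.defined
            else:
                assert r.defined
                assert r.gamma == pytest.approx((C - D) / (C + D))
                assert (r.concordant, r.discordant) == (C, D)

    @given(st.integers(0, 5000))
    @settings(max_examples=50, derandomize=True)
    def test_negating_choice_coding_negates_gamma(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 100, 12)
        choices = rng.integers(0, 2, 12)
        a = goodman_kruskal_gamma(scores, choices)
        b = goodman_kruskal_gamma(scores, 1 - choices)
        if a.defined:
            assert b.gamma == pytest.approx(-a.gamma)
        else:
            assert not b.defined

    def test_group_test_drops_undefined_gammas(self):
        rng = np.random.default_rng(6)
        gammas = list(rng.normal(-0.5, 0.2, 71)) + [None]
        r = gamma_group_test(gammas)
        assert r.df == 70
        assert abs(r.effect_size - abs(np.mean(gammas[:71])) / np.std(
            gammas[:71], ddof=1)) < 1e-12

    def test_all_equal_gammas_zero_variance(self):
        r = gamma_group_test([-1.0, -1.0, -1.0])
        assert r.zero_variance


class TestLoftusMasson:
    def test_identical_condition_differences_zero_half_width(self):
        base = np.array([[10.0, 14.0], [20.0, 24.0], [7.0, 11.0]])
        ci = loftus_masson_ci(base)
        assert ci.half_width == pytest.approx(0.0, abs=1e-9)

    def test_hand_decomposition_on_4x2_matrix(self):
        Y = np.array([[3.0, 7.0], [5.0, 6.0], [2.0, 9.0], [4.0, 4.0]])
        ci = loftus_masson_ci(Y)
        # brute-force two-way decomposition
        grand = Y.mean()
        resid = Y - Y.mean(1, keepdims=True) - Y.mean(0, keepdims=True) + grand
        ms = (resid**2).sum() / 3
        from scipy import stats

        expected = stats.t.ppf(0.975, 3) * np.sqrt(ms / 4)
        assert ci.half_width == pytest.approx(expected, rel=1e-12)
        assert ci.error_df == 3

    def test_error_df_formula(self):
        rng = np.random.default_rng(1)
        ci = loftus_masson_ci(rng.normal(size=(72, 2)))
        assert ci.error_df == 71


class TestPower:
    def test_reference_one_sided_within_design(self):
        r = required_n_paired_t(0.35, alpha=0.05, power=0.90, sided="one")
        assert r.required_n == 72

    def test_two_sided_medium_effect(self):
        r = required_n_paired_t(0.5, alpha=0.05, power=0.80, sided="two")
        assert r.required_n == 34

    def test_matches_statsmodels_solver(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        n_float = smp.TTestPower().solve_power(
            effect_size=0.35, alpha=0.05, power=0.90, alternative="larger"
        )
        r = required_n_paired_t(0.35, 0.05, 0.90, "one")
        assert r.required_n == int(np.ceil(n_float))

    @pytest.mark.parametrize(
        "d_z, alpha, power, sided",
        [(0.35, 0.05, 0.90, "one"), (0.5, 0.05, 0.80, "two"),
         (0.2, 0.01, 0.95, "one"), (0.8, 0.10, 0.85, "two")],
    )
    def test_returned_n_is_the_boundary(self, d_z, alpha, power, sided):
        r = required_n_paired_t(d_z, alpha, power, sided)
        assert r.achieved_power >= power
        assert paired_t_power(r.required_n - 1, d_z, alpha, sided) < power

    def test_power_nondecreasing_in_n(self):
        powers = [paired_t_power(n, 0.35, 0.05, "one") for n in range(5, 201)]
        assert np.all(np.diff(powers) >= -1e-12)

    def test_zero_effect_rejected(self):
        with pytest.raises(StatsDomainError):
            required_n_paired_t(0.0)


class TestRestudyRates:
    def test_worked_example_half(self):
        trials = pd.DataFrame(
            {
                "participant": ["p1"] * 24,
                "accuracy": ["correct"] * 24,
                "restudy_choice": [1] * 12 + [0] * 12,
            }
        )
        out = restudy_rates_by_cell(trials, ["accuracy"])
        assert out.loc[0, "rate"] == pytest.approx(0.5)
        assert out.loc[0, "n_trials"] == 24

    def test_zero_chosen_gives_zero_rate(self):
        trials = pd.DataFrame(
            {"participant": ["p"] * 5, "cell": ["a"] * 5, "restudy_choice": [0] * 5}
        )
        out = restudy_rates_by_cell(trials, ["cell"])
        assert out.loc[0, "rate"] == 0.0

    def test_three_participant_fixture_matches_hand_tally(self):
        rows = []
        # p1: cell a 2/4 chosen, cell b 1/2; p2: a 0/3; p3: b 2/2
        rows += [("p1", "a", c) for c in (1, 1, 0, 0)]
        rows += [("p1", "b", c) for c in (1, 0)]
        rows += [("p2", "a", c) for c in (0, 0, 0)]
        rows += [("p3", "b", c) for c in (1, 1)]
        trials = pd.DataFrame(rows, columns=["participant", "cell", "restudy_choice"])
        out = restudy_rates_by_cell(trials, ["cell"]).set_index(
            ["participant", "cell"]
        )
        assert out.loc[("p1", "a"), "rate"] == 0.5
        assert out.loc[("p1", "b"), "rate"] == 0.5
        assert out.loc[("p2", "a"), "rate"] == 0.0
        assert out.loc[("p3", "b"), "rate"] == 1.0
        assert ("p2", "b") not in out.index
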