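"""ANOVA, Bonferroni compact letter display and effect summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenovol import phenostats as ps
from phenovol.errors import InvalidInputError, UnsupportedDesignError

FIXTURE_3GROUPS = {
    "a": np.array([18.2, 20.1, 19.7, 21.3, 18.9]),
    "b": np.array([22.4, 23.1, 21.8, 24.0, 22.7]),
    "c": np.array([19.0, 19.8, 20.5, 18.7, 20.2]),
}


def brute_force_one_way(groups):
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


class TestOneWayAnova:
    def test_identical_observations_give_zero_f(self):
        res = ps.one_way_anova({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.f["group"] == 0.0
        assert res.p["group"] == 1.0

    def test_matches_brute_force_decomposition(self):
        res = ps.one_way_anova(FIXTURE_3GROUPS)
        f, dfb, dfw = brute_force_one_way(FIXTURE_3GROUPS)
        assert res.f["group"] == pytest.approx(f, rel=1e-9)
        assert res.df["group"] == dfb
        assert res.residual_df == dfw

    def test_parametric_p_agrees_with_permutation_oracle(self):
        """10,000 label shuffles reproduce the F-distribution p value."""
        rng = np.random.default_rng(2024)
        res = ps.one_way_anova(FIXTURE_3GROUPS)
        allv = np.concatenate(list(FIXTURE_3GROUPS.values()))
        sizes = [len(v) for v in FIXTURE_3GROUPS.values()]
        f_obs = res.f["group"]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(allv)
            groups, i = {}, 0
            for gi, s in enumerate(sizes):
                groups[gi] = perm[i:i + s]
                i += s
            if brute_force_one_way(groups)[0] >= f_obs:
                count += 1
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(res.p["group"] * (1 - res.p["group"]) / n_perm)
        assert abs(p_perm - res.p["group"]) <= mc_err + 1e-3

    def test_zero_residual_variance_warns_p_zero(self):
        with pytest.warns(UserWarning):
            res = ps.one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p["group"] == 0.0

    def test_f_invariant_under_shift_and_scale(self):
        base = ps.one_way_anova(FIXTURE_3GROUPS).f["group"]
        shifted = {g: v + 100.0 for g, v in FIXTURE_3GROUPS.items()}
        scaled = {g: v * 7.3 for g, v in FIXTURE_3GROUPS.items()}
        assert ps.one_way_anova(shifted).f["group"] == pytest.approx(base)
        assert ps.one_way_anova(scaled).f["group"] == pytest.approx(base)

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            ps.one_way_anova({"a": [1.0, 2.0]})
        with pytest.raises(InvalidInputError):
            ps.one_way_anova({"a": [1.0], "b": [2.0, 3.0]})


def balanced_frame(effects_a, effects_b, interaction=0.0, reps=3, noise=0.0,
                   seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, ea in enumerate(effects_a):
        for j, eb in enumerate(effects_b):
            for _ in range(reps):
                y = 10 + ea + eb + (interaction if i == j == 1 else 0.0)
                rows.append(dict(treatment=f"t{i}", time=f"d{j}",
                                 y=y + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_additive_noise_free_design_has_zero_interaction_f(self):
        df = balanced_frame([0, 2, 4], [0, 3], noise=0.5, seed=1)
        res = ps.two_way_anova(df, "y", "treatment", "time")
        assert res.f["treatment:time"] == pytest.approx(0.0, abs=5.0)
        assert res.p["treatment"] < 0.001

    def test_matches_brute_force_balanced_decomposition(self):
        df = balanced_frame([0, 2, 4], [0, 3], interaction=1.5, noise=1.0,
                            seed=7)
        res = ps.two_way_anova(df, "y", "treatment", "time")
        # hand-computed balanced two-way sums of squares
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_a = sum(len(s) * (s["y"].mean() - grand) ** 2
                   for _, s in df.groupby("treatment"))
        ss_b = sum(len(s) * (s["y"].mean() - grand) ** 2
                   for _, s in df.groupby("time"))
        ss_cell = sum(len(s) * (s["y"].mean() - grand) ** 2
                      for _, s in df.groupby(["treatment", "time"]))
        ss_ab = ss_cell - ss_a - ss_b
        ss_err = sum(((s["y"] - s["y"].mean()) ** 2).sum()
                     for _, s in df.groupby(["treatment", "time"]))
        df_a, df_b = 2, 1
        df_ab = df_a * df_b
        df_err = len(y) - 6
        assert res.f["treatment"] == pytest.approx(
            (ss_a / df_a) / (ss_err / df_err), rel=1e-9)
        assert res.f["time"] == pytest.approx(
            (ss_b / df_b) / (ss_err / df_err), rel=1e-9)
        assert res.f["treatment:time"] == pytest.approx(
            (ss_ab / df_ab) / (ss_err / df_err), rel=1e-9)

    def test_unbalanced_design_rejected(self):
        df = balanced_frame([0, 2], [0, 3], noise=1.0)
        res = ps.two_way_anova(df, "y", "treatment", "time")  # balanced: fine
        assert res.residual_df > 0
        with pytest.raises(UnsupportedDesignError):
            ps.two_way_anova(df.iloc[:-1], "y", "treatment", "time")

    def test_single_level_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame([
            dict(treatment=t, time="d0", y=rng.normal({"t0": 0, "t1": 2}[t], 1))
            for t in ["t0", "t1"] for _ in range(6)
        ])
        groups = {t: s["y"].to_numpy() for t, s in df.groupby("treatment")}
        one_way_f = ps.one_way_anova(groups).f["group"]
        # with a single time level the treatment main effect is the one-way F
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        fit = smf.ols("y ~ C(treatment)", data=df).fit()
        assert anova_lm(fit, typ=1).loc["C(treatment)", "F"] == pytest.approx(
            one_way_f, rel=1e-9)


class TestBonferroniLetters:
    def test_clearly_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        groups = {"low": rng.normal(10, 0.1, 9), "high": rng.normal(50, 0.1, 9)}
        letters = ps.bonferroni_letters(groups).letters
        assert set(letters["low"]) & set(letters["high"]) == set()

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(10, 1.0, 9) for g in "abcde"}
        letters = ps.bonferroni_letters(groups).letters
        shared = set.intersection(*(set(v) for v in letters.values()))
        assert shared, f"expected a common letter, got {letters}"

    def test_letter_display_consistent_with_adjusted_p_matrix(self):
        """Exhaustive check of the compact-letter-display contract."""
        rng = np.random.default_rng(12)
        groups = {
            "g1": rng.normal(10, 1, 9), "g2": rng.normal(10.5, 1, 9),
            "g3": rng.normal(14, 1, 9), "g4": rng.normal(14.2, 1, 9),
            "g5": rng.normal(25, 1, 9),
        }
        res = ps.bonferroni_letters(groups, alpha=0.05)
        for (a, b), p in res.adjusted_p.items():
            share = set(res.letters[a]) & set(res.letters[b])
            if p < res.alpha:
                assert not share, f"{a},{b} differ (p={p:.3g}) but share {share}"
            else:
                assert share, f"{a},{b} do not differ (p={p:.3g}) but no letter"

    def test_single_group_gets_single_letter(self):
        res = ps.bonferroni_letters({"only": np.array([1.0, 2.0, 3.0])})
        assert res.letters == {"only": "a"}

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_adjusted_p_bounds(self, seed):
        """Bonferroni-adjusted p is >= raw Welch p and capped at 1."""
        from scipy import stats
        rng = np.random.default_rng(seed)
        groups = {g: rng.normal(0, 1, 6) for g in "abcd"}
        adj = ps.pairwise_bonferroni(groups)
        for (a, b), p in adj.items():
            raw = stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            assert p >= raw - 1e-15
            assert p <= 1.0


class TestEffectSummaries:
    def test_percent_change_of_printed_harvest_means(self):
        assert ps.percent_change(55.9, 64.84) == pytest.approx(16.0, abs=0.01)

    def test_percent_change_trivia(self):
        assert ps.percent_change(10.0, 10.0) == 0.0
        assert ps.percent_change(10.0, 20.0) == 100.0
        with pytest.raises(InvalidInputError):
            ps.percent_change(0.0, 5.0)

    def test_group_summary_mean_and_se(self):
        s, = ps.group_summary({"g": np.array([1.0, 2.0, 3.0])})
        assert s.mean == pytest.approx(2.0)
        assert s.se == pytest.approx(1.0 / np.sqrt(3))
        assert s.n == 3


class TestStressClassification:
    @pytest.mark.parametrize("fvfm,expected", [
        (0.84, "unstressed"),
        (0.83, "stressed"),   # strict inequality at the boundary
        (0.50, "stressed"),
    ])
    def test_fvfm_threshold(self, fvfm, expected):
        assert ps.classify_stress(fvfm) == expected

    def test_accepts_fluorescence_record(self):
        from phenovol.assaycalc import FluorescenceRecord
        assert ps.classify_stress(FluorescenceRecord(fvfm=0.9)) == "unstressed"
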