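"""ANOVA decompositions, simple effects, summary-table ANOVA, OLS + VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emosafe import (
    anova_from_summary,
    multiple_regression,
    one_way_anova,
    repeated_measures_anova,
    simple_effects,
    summarize_cells,
    two_way_anova,
)

from oracles import one_way_ss, ols_normal_equations

HAND_GROUPS = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]


def _balanced_table(rng, n_per_cell=8, a_effect=0.0, b_effect=0.0, ab_effect=0.0):
    rows = []
    for ai, a in enumerate(("neutral", "fear", "anger")):
        for bi, b in enumerate(("low", "high")):
            mu = a_effect * ai + b_effect * bi + ab_effect * ai * bi
            for _ in range(n_per_cell):
                rows.append((a, b, mu + rng.standard_normal()))
    df = pd.DataFrame(rows, columns=["a", "b", "y"])
    return df["y"].to_numpy(), df["a"].to_numpy(), df["b"].to_numpy()


class TestOneWay:
    def test_hand_computed_fixture(self):
        """{1,2,3},{2,3,4},{3,4,5}: SSB = 6 (2 df), SSW = 6 (6 df), F = 3."""
        values = [v for g in HAND_GROUPS for v in g]
        labels = [f"g{i}" for i, g in enumerate(HAND_GROUPS) for _ in g]
        res = one_way_anova(values, labels)
        ssb, ssw, df_b, df_w, f = one_way_ss(HAND_GROUPS)
        assert (ssb, ssw, df_b, df_w, f) == (6.0, 6.0, 2, 6, 3.0)
        eff = res.effect("group")
        assert eff.F == pytest.approx(3.0, abs=1e-12)
        assert (eff.df, res.df_error) == (2, 6)
        assert eff.ss == pytest.approx(6.0)
        assert res.ss_error == pytest.approx(6.0)

    def test_equal_means_zero_f(self):
        res = one_way_anova([1, 2, 3, 2, 3, 1, 3, 1, 2], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.effect("group").F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(15) + 0.8
        res = one_way_anova(
            np.concatenate([x, y]), ["a"] * 12 + ["b"] * 15
        )
        t, p = stats.ttest_ind(x, y, equal_var=True)
        assert res.effect("group").F == pytest.approx(t**2, rel=1e-10)
        assert res.effect("group").p == pytest.approx(p, rel=1e-10)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestTwoWay:
    def test_ss_and_df_additivity(self, rng):
        y, fa, fb = _balanced_table(rng, a_effect=1.0, b_effect=0.5)
        res = two_way_anova(y, fa, fb)
        ss_sum = sum(e.ss for e in res.effects.values()) + res.ss_error
        assert ss_sum == pytest.approx(res.ss_total, rel=1e-8)
        df_sum = sum(e.df for e in res.effects.values()) + res.df_error
        assert df_sum == len(y) - 1

    def test_eta_squared_shares_sum_to_one(self, rng):
        y, fa, fb = _balanced_table(rng, a_effect=2.0, ab_effect=0.7)
        res = two_way_anova(y, fa, fb)
        shares = sum(e.eta_sq for e in res.effects.values())
        shares += res.ss_error / res.ss_total
        assert shares == pytest.approx(1.0, abs=1e-10)

    def test_matches_statsmodels_decomposition(self, rng):
        """Cross-check the hand decomposition against an independent OLS
        ANOVA (balanced design, so Type II equals the classical SS)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y, fa, fb = _balanced_table(rng, a_effect=1.2, b_effect=0.4, ab_effect=0.3)
        res = two_way_anova(y, fa, fb)
        fit = smf.ols(
            "y ~ C(a) * C(b)", data=pd.DataFrame({"y": y, "a": fa, "b": fb})
        ).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.effect("emotion").ss == pytest.approx(
            tab.loc["C(a)", "sum_sq"], rel=1e-8
        )
        assert res.effect("psycap").ss == pytest.approx(
            tab.loc["C(b)", "sum_sq"], rel=1e-8
        )
        assert res.effect("emotion:psycap").F == pytest.approx(
            tab.loc["C(a):C(b)", "F"], rel=1e-8
        )

    def test_constant_second_factor_collapses_to_one_way(self, rng):
        """With a single-level factor B, the A effect must reproduce the
        one-way ANOVA exactly (df bookkeeping aside)."""
        y = rng.standard_normal(30)
        fa = np.repeat(["x", "y", "z"], 10)
        one = one_way_anova(y, fa)
        # a degenerate one-level B makes SS_B = SS_AB = 0
        res = two_way_anova(y, fa, np.repeat("only", 30), unbalanced="type2")
        assert res.effect("psycap").ss == pytest.approx(0.0, abs=1e-8)
        assert res.effect("emotion").ss == pytest.approx(
            one.effect("group").ss, rel=1e-10
        )

    def test_null_tables_rarely_reject(self, rng):
        """Under a pure-noise table, each of the three 5%-level tests is
        separately calibrated, so all three stay above 0.05 in about
        0.95**3 ~ 86% of tables (slightly more, as they share an error
        term); the bound below is ~3 sigma under that rate."""
        hits = 0
        for _ in range(200):
            y, fa, fb = _balanced_table(rng, n_per_cell=5)
            res = two_way_anova(y, fa, fb)
            hits += all(e.p > 0.05 for e in res.effects.values())
        assert hits / 200 >= 0.80

    def test_empty_cell_rejected(self):
        y = np.arange(8.0)
        fa = np.array(["a"] * 4 + ["b"] * 4)
        fb = np.array(["l", "l", "h", "h", "l", "l", "l", "l"])
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(y, fa, fb)

    def test_unbalanced_layout_needs_explicit_mode(self, rng):
        y, fa, fb = _balanced_table(rng)
        fa = fa.copy()
        fa[0] = "fear"  # unbalance one cell
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(y, fa, fb)
        res = two_way_anova(y, fa, fb, unbalanced="type2")
        assert set(res.effects) == {"emotion", "psycap", "emotion:psycap"}


class TestSimpleEffects:
    def test_flat_focal_factor_gives_zero_f(self, rng):
        y, fa, fb = _balanced_table(rng)
        # make dv constant across focal levels within moderator level 'low'
        mask = fb == "low"
        y = y.copy()
        y[mask] = 1.0
        res = simple_effects(y, fa, fb, level="low")
        assert res["low"].effects["emotion"].F == pytest.approx(0.0, abs=1e-12)

    def test_within_error_reproduces_restricted_one_way(self, rng):
        y, fa, fb = _balanced_table(rng, a_effect=1.0)
        res = simple_effects(y, fa, fb, error="within")
        for level in ("low", "high"):
            mask = fb == level
            one = one_way_anova(y[mask], fa[mask])
            assert res[level].effects["emotion"].F == pytest.approx(
                one.effect("group").F, rel=1e-10
            )

    def test_pooled_error_uses_full_model_msw(self, rng):
        y, fa, fb = _balanced_table(rng, a_effect=1.0, ab_effect=0.5)
        full = two_way_anova(y, fa, fb, a_name="focal", b_name="moderator")
        res = simple_effects(y, fa, fb, error="pooled")
        for level in ("low", "high"):
            mask = fb == level
            sub_y, sub_f = y[mask], fa[mask]
            lm = sub_y.mean()
            ss = sum(
                (sub_f == fl).sum() * (sub_y[sub_f == fl].mean() - lm) ** 2
                for fl in set(sub_f)
            )
            expected_f = (ss / 2) / full.ms_error
            assert res[level].effects["emotion"].F == pytest.approx(
                expected_f, rel=1e-10
            )

    def test_significant_effects_carry_directed_posthoc(self, rng):
        y, fa, fb = _balanced_table(rng, n_per_cell=12)
        y = y + np.where(fa == "fear", 3.0, 0.0)  # strong fear elevation
        res = simple_effects(y, fa, fb)
        for level in ("low", "high"):
            comps = res[level].posthoc
            assert comps, "significant simple effect must include post-hoc"
            directions = {c.direction for c in comps}
            assert any(d.startswith("fear >") for d in directions)

    def test_unknown_level_rejected(self, rng):
        y, fa, fb = _balanced_table(rng)
        with pytest.raises(ValueError, match="unknown moderator level"):
            simple_effects(y, fa, fb, level="medium")


class TestRepeatedMeasures:
    def _paired_data(self, rng, n_subjects=12, subject_sd=2.0):
        subj = np.repeat([f"s{i}" for i in range(n_subjects)], 3)
        fac = np.tile(["neutral", "fear", "anger"], n_subjects)
        subject_effect = np.repeat(rng.normal(0, subject_sd, n_subjects), 3)
        y = (
            subject_effect
            + np.where(fac == "fear", 1.0, 0.0)
            + rng.standard_normal(len(fac))
        )
        return y, subj, fac

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        y, subj, fac = self._paired_data(rng)
        res = repeated_measures_anova(y, subj, fac)
        frame = pd.DataFrame({"y": y, "subj": subj, "fac": fac})
        tab = AnovaRM(frame, "y", "subj", within=["fac"]).fit().anova_table
        assert res.effect("emotion").F == pytest.approx(
            tab.loc["fac", "F Value"], rel=1e-8
        )
        assert res.effect("emotion").p == pytest.approx(
            tab.loc["fac", "Pr > F"], rel=1e-6
        )
        assert (res.effect("emotion").df, res.df_error) == (2, 22)

    def test_more_powerful_than_between_subjects_under_subject_noise(self, rng):
        """Large stable subject differences inflate the between-subjects
        error but are removed by the within-subject decomposition."""
        y, subj, fac = self._paired_data(rng, subject_sd=4.0)
        within = repeated_measures_anova(y, subj, fac)
        between = one_way_anova(y, fac)
        assert within.effect("emotion").F > between.effect("group").F

    def test_incomplete_subject_rejected(self, rng):
        y, subj, fac = self._paired_data(rng)
        with pytest.raises(ValueError, match="once per level"):
            repeated_measures_anova(y[:-1], subj[:-1], fac[:-1])


class TestAnovaFromSummary:
    def test_round_trip_matches_raw_two_way(self, rng):
        y, fa, fb = _balanced_table(rng, a_effect=0.8, b_effect=0.3)
        raw = two_way_anova(y, fa, fb)
        summary = anova_from_summary(summarize_cells(y, fa, fb), design="two-way")
        for name in raw.effects:
            assert summary.effect(name).F == pytest.approx(
                raw.effect(name).F, rel=1e-8
            )
            assert summary.effect(name).p == pytest.approx(
                raw.effect(name).p, rel=1e-8
            )

    def test_round_trip_on_random_balanced_tables(self, rng):
        for _ in range(100):
            y, fa, fb = _balanced_table(
                rng,
                n_per_cell=int(rng.integers(3, 9)),
                a_effect=float(rng.normal()),
                b_effect=float(rng.normal()),
                ab_effect=float(rng.normal()),
            )
            raw = two_way_anova(y, fa, fb)
            summ = anova_from_summary(summarize_cells(y, fa, fb), "two-way")
            for name in raw.effects:
                assert summ.effect(name).F == pytest.approx(
                    raw.effect(name).F, rel=1e-7
                )

    def test_equal_cell_means_zero_f(self):
        cells = {(a, b): (5.0, 1.0, 10) for a in "xyz" for b in "lh"}
        res = anova_from_summary(cells, "two-way")
        for eff in res.effects.values():
            assert eff.F == pytest.approx(0.0, abs=1e-12)

    def test_one_way_hand_fixture(self):
        cells = {
            f"g{i}": (np.mean(g), np.std(g, ddof=1), len(g))
            for i, g in enumerate(HAND_GROUPS)
        }
        res = anova_from_summary(cells, design="one-way")
        assert res.effect("group").F == pytest.approx(3.0, rel=1e-10)

    def test_missing_cell_rejected(self):
        cells = {("a", "l"): (1.0, 1.0, 5), ("a", "h"): (1.0, 1.0, 5),
                 ("b", "l"): (1.0, 1.0, 5)}
        with pytest.raises(ValueError, match="missing cells"):
            anova_from_summary(cells, "two-way")


class TestMultipleRegression:
    def test_exact_linear_response(self, rng):
        x = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = 2.0 + x @ [1.0, -2.0, 0.5]
        res = multiple_regression(y, x)
        assert res.r_squared == pytest.approx(1.0)
        assert np.linalg.norm(res.residuals) < 1e-10
        assert res.intercept == pytest.approx(2.0)

    def test_matches_normal_equations(self, rng):
        x = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = 1.0 + x @ [0.5, -1.0, 2.0] + rng.standard_normal(40)
        res = multiple_regression(y, x)
        expected = ols_normal_equations(x.values, y)  # [intercept, a, b, c]
        got = res.table.loc[["const", "a", "b", "c"], "B"].to_numpy()
        assert got == pytest.approx(expected, abs=1e-8)

    def test_orthogonal_predictors_unit_vif(self):
        n = 16
        t = np.arange(n)
        x = pd.DataFrame(
            {
                "s1": np.sin(2 * np.pi * t / n),
                "c1": np.cos(2 * np.pi * t / n),
                "s2": np.sin(4 * np.pi * t / n),
            }
        )
        y = x["s1"] + 0.1 * np.random.default_rng(0).standard_normal(n)
        res = multiple_regression(y, x)
        assert res.table.loc[["s1", "c1", "s2"], "vif"].to_numpy() == pytest.approx(
            np.ones(3), abs=1e-10
        )

    def test_collinear_predictors_rejected(self, rng):
        x = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        x["c"] = x["a"] + x["b"]
        with pytest.raises(ValueError, match="rank-deficient"):
            multiple_regression(rng.standard_normal(20), x)

    def test_too_few_rows_rejected(self, rng):
        x = pd.DataFrame(rng.standard_normal((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="rows"):
            multiple_regression(np.zeros(4), x)
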