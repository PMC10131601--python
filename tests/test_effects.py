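"""Effect estimators: paired/unpaired tests, decomposition, ED split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import claimsdid as cd
from claimsdid.config import CATEGORIES
from conftest import make_claims


def summaries_from_changes(changes, group="treated"):
    n = len(changes)
    return pd.DataFrame(
        {
            "member_id": [f"{group[0]}{i}" for i in range(n)],
            "group": group,
            "anchor_month": 15,
            "pre_months": 12,
            "post_months": 12,
            "pre_pupm": 100.0,
            "post_pupm": 100.0 + np.asarray(changes, dtype=float),
            "change": np.asarray(changes, dtype=float),
        }
    )


class TestWithinGroupChange:
    def test_mean_and_sign(self):
        est = cd.within_group_change(summaries_from_changes([-5.0, -10.0, -15.0]))
        assert est.estimate == pytest.approx(-10.0)
        assert est.t_stat < 0

    def test_all_zero_changes_convention(self):
        est = cd.within_group_change(summaries_from_changes([0.0, 0.0, 0.0]))
        assert est.estimate == 0.0
        assert est.p_value == 1.0

    def test_matches_paired_ttest(self):
        rng = np.random.default_rng(1)
        changes = rng.normal(-3, 10, 50)
        est = cd.within_group_change(summaries_from_changes(changes))
        ref = stats.ttest_1samp(changes, 0.0)
        assert est.t_stat == pytest.approx(ref.statistic)
        assert est.p_value == pytest.approx(ref.pvalue)
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_type_one_error_near_nominal(self):
        # Null changes: the paired test rejects at ~alpha over replicates.
        rng = np.random.default_rng(7)
        rejections = sum(
            cd.within_group_change(
                summaries_from_changes(rng.normal(0, 5, 40))
            ).p_value < 0.05
            for _ in range(400)
        )
        assert rejections / 400 == pytest.approx(0.05, abs=0.03)


class TestDifferenceInDifferences:
    def test_printed_group_changes_compose_to_ten(self):
        # comparison +2 and treated -8 PUPM mean changes -> $10 savings.
        t = summaries_from_changes([-7.0, -9.0], "treated")
        c = summaries_from_changes([1.0, 3.0], "comparison")
        est = cd.difference_in_differences(t, c)
        assert est.estimate == 10.0

    def test_identical_groups_give_zero_and_p_one(self):
        t = summaries_from_changes([4.0, 4.0], "treated")
        c = summaries_from_changes([4.0, 4.0], "comparison")
        est = cd.difference_in_differences(t, c)
        assert est.estimate == 0.0
        assert est.p_value == 1.0
        assert est.t_stat == 0.0

    def test_swapping_groups_negates_estimate(self):
        rng = np.random.default_rng(2)
        t = summaries_from_changes(rng.normal(-8, 5, 30), "treated")
        c = summaries_from_changes(rng.normal(2, 5, 30), "comparison")
        a = cd.difference_in_differences(t, c)
        b = cd.difference_in_differences(c, t)
        assert a.estimate == pytest.approx(-b.estimate)
        assert a.p_value == pytest.approx(b.p_value)

    def test_welch_test_and_ci_consistency(self):
        rng = np.random.default_rng(3)
        t = summaries_from_changes(rng.normal(-8, 5, 40), "treated")
        c = summaries_from_changes(rng.normal(2, 9, 35), "comparison")
        est = cd.difference_in_differences(t, c)
        ref = stats.ttest_ind(c["change"], t["change"], equal_var=False)
        assert est.p_value == pytest.approx(ref.pvalue)
        assert (est.p_value < 0.05) == (est.ci_low > 0 or est.ci_high < 0)

    def test_small_group_errors(self):
        t = summaries_from_changes([-8.0], "treated")
        c = summaries_from_changes([1.0, 3.0], "comparison")
        with pytest.raises(ValueError):
            cd.difference_in_differences(t, c)


class TestCategoryBreakdown:
    def _with_categories(self, df, spend_by_cat):
        for cat in CATEGORIES:
            pre, post = spend_by_cat.get(cat, (0.0, 0.0))
            df[f"pre_{cat}"] = pre
            df[f"post_{cat}"] = post
        return df

    def test_single_category_equals_overall(self):
        rng = np.random.default_rng(4)
        t = summaries_from_changes(rng.normal(-8, 4, 25), "treated")
        c = summaries_from_changes(rng.normal(2, 4, 25), "comparison")
        for df in (t, c):
            self._with_categories(df, {})
            df["pre_specialist"] = df["pre_pupm"]
            df["post_specialist"] = df["post_pupm"]
        table = cd.category_breakdown(t, c).set_index("label")
        assert table.loc["specialist", "estimate"] == pytest.approx(
            table.loc["overall", "estimate"]
        )

    def test_all_zero_category_estimates_zero(self):
        t = self._with_categories(summaries_from_changes([-1.0, -2.0], "treated"), {})
        c = self._with_categories(summaries_from_changes([1.0, 2.0], "comparison"), {})
        table = cd.category_breakdown(t, c).set_index("label")
        assert table.loc["laboratory", "estimate"] == 0.0

    def test_unknown_category_errors(self):
        t = self._with_categories(summaries_from_changes([-1.0, -2.0], "treated"), {})
        c = self._with_categories(summaries_from_changes([1.0, 2.0], "comparison"), {})
        with pytest.raises(ValueError, match="acupuncture"):
            cd.category_breakdown(t, c, categories=["acupuncture"])

    def test_category_savings_sum_to_overall_without_capping(self, midsize_cohort):
        # Additivity of the decomposition holds exactly when no member hits
        # the cap; capping is disabled by setting the percentile to 100.
        cfg, members, claims = midsize_cohort
        res = cd.evaluate_cohort(
            members, claims, study_start=0, study_end=cfg.n_months - 1, seed=42,
            with_categories=False,
        )
        filtered = cd.filter_claims(claims)
        s = cd.summarize_members(
            members, filtered, res.pairs, cfg.n_months - 1, cap_percentile=100.0
        )
        t = s[s["group"] == "treated"]
        c = s[s["group"] == "comparison"]
        table = cd.category_breakdown(t, c).set_index("label")
        cat_sum = table.loc[list(CATEGORIES), "estimate"].sum()
        assert cat_sum == pytest.approx(table.loc["overall", "estimate"], abs=1e-6)


class TestClassifyED:
    def _table(self):
        return pd.DataFrame(
            {
                "diag_code": ["A", "B"],
                "p_emergent": [0.3, 0.2],
                "p_nonemergent": [0.7, 0.8],
                "p_other": [0.0, 0.0],
            }
        )

    def test_linear_split(self):
        claims = make_claims([("M0", 5, "ED", 100.0, False, False, "A")])
        out = cd.classify_ed(claims, self._table())
        assert out["emergent_usd"].iloc[0] == pytest.approx(30.0)
        assert out["nonemergent_usd"].iloc[0] == pytest.approx(70.0)

    def test_fully_emergent_row(self):
        table = pd.DataFrame(
            {"diag_code": ["X"], "p_emergent": [1.0], "p_nonemergent": [0.0], "p_other": [0.0]}
        )
        claims = make_claims([("M0", 5, "ED", 42.0, False, False, "X")])
        out = cd.classify_ed(claims, table)
        assert out["emergent_usd"].iloc[0] == pytest.approx(42.0)
        assert out["nonemergent_usd"].iloc[0] == 0.0

    def test_hand_summed_totals(self):
        table = pd.DataFrame(
            {
                "diag_code": ["A", "B"],
                "p_emergent": [0.2, 0.6],
                "p_nonemergent": [0.8, 0.4],
                "p_other": [0.0, 0.0],
            }
        )
        claims = make_claims(
            [
                ("M0", 5, "ED", 50.0, False, False, "A"),
                ("M0", 6, "ED", 50.0, False, False, "B"),
            ]
        )
        out = cd.classify_ed(claims, table)
        assert out["emergent_usd"].sum() == pytest.approx(40.0)
        assert out["nonemergent_usd"].sum() == pytest.approx(60.0)

    def test_unknown_code_goes_to_other_with_warning(self, caplog):
        claims = make_claims([("M0", 5, "ED", 100.0, False, False, "ZZZ")])
        with caplog.at_level("WARNING"):
            out = cd.classify_ed(claims, self._table())
        assert out["other_usd"].iloc[0] == pytest.approx(100.0)
        assert any("ZZZ" not in r.message and "absent" in r.message for r in caplog.records)

    def test_unknown_code_error_policy(self):
        claims = make_claims([("M0", 5, "ED", 100.0, False, False, "ZZZ")])
        with pytest.raises(ValueError, match="ZZZ"):
            cd.classify_ed(claims, self._table(), unknown="error")

    def test_bundled_table_is_valid(self):
        table = cd.load_ed_table()
        probs = table[["p_emergent", "p_nonemergent", "p_other"]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert table["diag_code"].is_unique


class TestAnnualize:
    def test_study_scale_savings(self):
        assert cd.annualize(10.0, 56_816, 12) == 6_817_920.0

    def test_per_user_year(self):
        assert cd.annualize(10.0, 1, 12) == 120.0

    def test_zero_savings(self):
        assert cd.annualize(0.0, 56_816, 12) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.annualize(-1.0, 10, 12)


class TestSubgroupEffect:
    def _setup(self):
        rng = np.random.default_rng(6)
        t = summaries_from_changes(rng.normal(-8, 3, 40), "treated")
        c = summaries_from_changes(rng.normal(2, 3, 40), "comparison")
        summaries = pd.concat([t, c], ignore_index=True)
        pairs = pd.DataFrame(
            {
                "treated_id": t["member_id"],
                "control_id": c["member_id"],
                "anchor_month": 15,
            }
        )
        return pairs, summaries

    def test_always_true_predicate_equals_overall(self):
        pairs, summaries = self._setup()
        t = summaries[summaries["group"] == "treated"]
        c = summaries[summaries["group"] == "comparison"]
        overall = cd.difference_in_differences(t, c)
        sub = cd.subgroup_effect(
            pairs, summaries, lambda df: pd.Series(True, index=df.index)
        )
        assert sub.estimate == pytest.approx(overall.estimate)
        assert sub.p_value == pytest.approx(overall.p_value)

    def test_empty_selection_errors(self):
        pairs, summaries = self._setup()
        with pytest.raises(ValueError, match="fewer than 2"):
            cd.subgroup_effect(
                pairs, summaries, lambda df: pd.Series(False, index=df.index)
            )

    def test_two_stratum_effect_recovery(self):
        # Treated changes -39 in the flagged stratum and -10 elsewhere;
        # the subgroup and complement estimates recover each stratum.
        rng = np.random.default_rng(8)
        flagged = [f"t{i}" in {f"t{j}" for j in range(20)} for i in range(60)]
        changes = np.where(flagged, rng.normal(-39, 2, 60), rng.normal(-10, 2, 60))
        t = summaries_from_changes(changes, "treated")
        c = summaries_from_changes(rng.normal(0, 2, 60), "comparison")
        summaries = pd.concat([t, c], ignore_index=True)
        pairs = pd.DataFrame(
            {"treated_id": t["member_id"], "control_id": c["member_id"], "anchor_month": 15}
        )
        in_sub = summaries["member_id"].isin([f"t{i}" for i in range(20)])
        sub = cd.subgroup_effect(pairs, summaries, lambda df: in_sub.loc[df.index])
        comp = cd.subgroup_effect(
            pairs, summaries,
            lambda df: ~in_sub.loc[df.index] & (df["group"] == "treated"),
        )
        assert sub.ci_low <= 39.0 <= sub.ci_high
        assert comp.ci_low <= 10.0 <= comp.ci_high


class TestNaiveContrast:
    def test_sign_convention(self):
        rng = np.random.default_rng(9)
        treated = rng.normal(90.0, 1.0, 200)
        pool = rng.normal(100.0, 1.0, 200)
        est = cd.naive_post_difference(treated, pool)
        assert est.estimate == pytest.approx(10.0, abs=0.5)
        assert est.p_value < 0.001
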