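"""Statistical battery vs textbook-formula oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isletmorph.stats import (
    grubbs_critical_value,
    grubbs_remove_outliers,
    pearson_correlation,
    rm_two_way_anova,
    significance_category,
    two_group_test,
    two_way_anova,
    variance_check_log_transform,
)


def student_t_oracle(x, y):
    """Textbook pooled-variance two-sample t test."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return t, p


def pearson_oracle(x, y):
    """Covariance-formula Pearson r with t-based two-tailed p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    n = len(x)
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def balanced_two_way_oracle(table: pd.DataFrame):
    """Hand computation of balanced two-way ANOVA F statistics."""
    grand = table["y"].mean()
    n = len(table)
    cells = table.groupby(["A", "B"])["y"]
    a_means = table.groupby("A")["y"].mean()
    b_means = table.groupby("B")["y"].mean()
    n_a = table.groupby("A").size()
    n_b = table.groupby("B").size()
    ss_a = float((n_a * (a_means - grand) ** 2).sum())
    ss_b = float((n_b * (b_means - grand) ** 2).sum())
    ss_cells = float((cells.size() * (cells.mean() - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = float(((table["y"] - cells.transform("mean")) ** 2).sum())
    df_a = len(a_means) - 1
    df_b = len(b_means) - 1
    df_ab = df_a * df_b
    df_err = n - len(a_means) * len(b_means)
    ms_err = ss_err / df_err
    return {
        "A": (ss_a / df_a) / ms_err,
        "B": (ss_b / df_b) / ms_err,
        "AB": (ss_ab / df_ab) / ms_err,
    }


class TestTwoGroupTest:
    def test_identical_groups_t_zero_p_one(self):
        res = two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.category == "ns"

    def test_forced_separation_significant(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, 2.0, 3.0]) + rng.normal(0, 1e-3, 3)
        y = x + 10.0
        res = two_group_test(x, y)
        assert res.p < 1e-3
        assert res.category == "significant"

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(10, 2, rng.integers(3, 12))
            y = rng.normal(11, 2, rng.integers(3, 12))
            res = two_group_test(x, y, check_variance=False)
            t, p = student_t_oracle(x, y)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_paired_uses_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + np.array([0.5, 0.6, 0.4, 0.5])
        res = two_group_test(x, y, paired=True)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t, abs=1e-12)

    def test_zero_variance_both_groups_raises(self):
        with pytest.raises(ValueError):
            two_group_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(5, 1, 8), rng.normal(6, 1, 8)
        r1 = two_group_test(x, y)
        r2 = two_group_test(x[::-1], y[::-1])
        assert r1.statistic == pytest.approx(r2.statistic)


class TestVarianceCheck:
    def test_equal_variance_no_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(10, 1, 20), rng.normal(12, 1, 20)]
        _, flag = variance_check_log_transform(groups)
        assert flag == "none"

    def test_tenfold_scale_difference_triggers_log(self):
        rng = np.random.default_rng(4)
        g1 = rng.lognormal(0, 0.3, 25)
        g2 = 10.0 * rng.lognormal(0, 0.9, 25)
        out, flag = variance_check_log_transform([g1, g2])
        assert flag == "log"
        np.testing.assert_allclose(out[0], np.log(g1))

    def test_transform_flag_recorded_in_result(self):
        rng = np.random.default_rng(5)
        g1 = rng.lognormal(0, 0.2, 30)
        g2 = 10.0 * rng.lognormal(1.0, 1.0, 30)
        res = two_group_test(g1, g2)
        assert res.transform == "log"

    def test_nonpositive_values_block_transform_with_warning(self):
        g1 = np.array([-1.0, 0.5, 1.0, 1.5, 0.1, 0.2])
        g2 = np.array([10.0, 200.0, 50.0, 400.0, 30.0, 700.0])
        with pytest.warns(UserWarning, match="non-positive"):
            _, flag = variance_check_log_transform([g1, g2])
        assert flag == "none"


class TestTwoWayAnova:
    def toy_table(self):
        # balanced 2 x 2, n = 3 per cell
        rows = []
        data = {
            ("wt", "young"): [10.0, 11.0, 12.0],
            ("wt", "old"): [13.0, 14.0, 16.0],
            ("ko", "young"): [15.0, 17.0, 16.0],
            ("ko", "old"): [22.0, 24.0, 23.0],
        }
        for (a, b), ys in data.items():
            rows += [{"A": a, "B": b, "y": y} for y in ys]
        return pd.DataFrame(rows)

    def test_matches_hand_computed_sums_of_squares(self):
        table = self.toy_table()
        res = two_way_anova(table, "y", "A", "B", posthoc="bonferroni")
        oracle = balanced_two_way_oracle(table)
        assert res.effects["A"]["F"] == pytest.approx(oracle["A"], abs=1e-8)
        assert res.effects["B"]["F"] == pytest.approx(oracle["B"], abs=1e-8)
        assert res.effects["A:B"]["F"] == pytest.approx(oracle["AB"], abs=1e-8)

    def test_all_equal_data_no_signal(self):
        rows = [
            {"A": a, "B": b, "y": 5.0}
            for a in "xy" for b in "uv" for _ in range(3)
        ]
        res = two_way_anova(pd.DataFrame(rows), "y", "A", "B", posthoc="bonferroni")
        for eff in res.effects.values():
            # zero between- and within-cell variance: F is 0/0, never positive
            assert not (eff["F"] > 1e-6)

    def test_pure_main_effect_detected(self):
        rng = np.random.default_rng(6)
        rows = []
        for a in ("wt", "ko"):
            for b in ("u", "v"):
                mu = 10.0 + (5.0 if a == "ko" else 0.0)
                rows += [
                    {"A": a, "B": b, "y": float(rng.normal(mu, 1.0))}
                    for _ in range(6)
                ]
        res = two_way_anova(pd.DataFrame(rows), "y", "A", "B", posthoc="tukey")
        assert res.effects["A"]["p"] < 0.01
        assert res.effects["B"]["p"] > 0.05
        assert res.posthoc is not None and len(res.posthoc) == 6  # all cell pairs

    def test_empty_cell_raises(self):
        table = self.toy_table()
        table = table[~((table["A"] == "ko") & (table["B"] == "old"))]
        with pytest.raises(ValueError, match="cells"):
            two_way_anova(table, "y", "A", "B", posthoc="bonferroni")

    def test_posthoc_must_be_named(self):
        with pytest.raises(ValueError):
            two_way_anova(self.toy_table(), "y", "A", "B", posthoc="fdr")


class TestRMTwoWayAnova:
    def percent_table(self, rng, shift_bin=None, n_mice=6):
        rows = []
        for g in ("ctrl", "treat"):
            for m in range(n_mice):
                base = rng.dirichlet([8, 4, 2, 1]) * 100
                if g == "treat" and shift_bin is not None:
                    base = base.copy()
                    moved = base[0] * 0.5
                    base[0] -= moved
                    base[shift_bin] += moved
                for b, v in enumerate(base):
                    rows.append(
                        {"group": g, "mouse": f"{g}{m}", "bin": f"b{b}", "pct": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_no_significant_contrast(self):
        rng = np.random.default_rng(7)
        table = self.percent_table(rng)
        res = rm_two_way_anova(table, "pct", "group", "bin", "mouse")
        assert (res.posthoc["p_adj"] > 0.05).all()

    def test_planted_shift_detected_in_largest_bin(self):
        rng = np.random.default_rng(8)
        table = self.percent_table(rng, shift_bin=3, n_mice=8)
        res = rm_two_way_anova(table, "pct", "group", "bin", "mouse")
        row = res.posthoc[res.posthoc["contrast"].str.contains("bin=b3")]
        assert float(row["p_adj"].iloc[0]) < 0.05

    def test_missing_cell_raises(self):
        rng = np.random.default_rng(9)
        table = self.percent_table(rng).iloc[1:]
        with pytest.raises(ValueError, match="cells"):
            rm_two_way_anova(table, "pct", "group", "bin", "mouse")


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 1, 30)
        res = pearson_correlation(x, -x + rng.normal(0, 1e-9, 30))
        assert res.r == pytest.approx(-1.0, abs=1e-6)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = 0.4 * x + rng.normal(0, 1, len(x))
            res = pearson_correlation(x, y)
            r, p = pearson_oracle(x, y)
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGrubbs:
    def test_tight_sample_keeps_everything(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05])
        kept, removed = grubbs_remove_outliers(vals)
        # oracle: max studentized deviation below the critical value
        g = np.abs(vals - vals.mean()).max() / vals.std(ddof=1)
        assert g < grubbs_critical_value(4)
        assert len(removed) == 0
        np.testing.assert_array_equal(kept, vals)

    def test_gross_outlier_removed(self):
        vals = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        g = np.abs(vals - vals.mean()).max() / vals.std(ddof=1)
        assert g > grubbs_critical_value(5)
        kept, removed = grubbs_remove_outliers(vals)
        assert list(removed) == [100.0]
        assert len(kept) == 4

    def test_constant_data_untouched(self):
        vals = np.ones(6)
        kept, removed = grubbs_remove_outliers(vals)
        assert len(removed) == 0 and len(kept) == 6

    def test_tiny_sample_warns_and_returns(self):
        with pytest.warns(UserWarning):
            kept, removed = grubbs_remove_outliers(np.array([1.0, 9.0]))
        assert len(kept) == 2 and len(removed) == 0

    def test_removal_cap_one_fifth(self):
        # two gross outliers but n=7 caps removals at 1
        vals = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 50.0, 60.0])
        kept, removed = grubbs_remove_outliers(vals)
        assert len(removed) <= 1

    def test_critical_value_formula(self):
        # spot-check against the t-based closed form at n=10, alpha=0.05
        n, alpha = 10, 0.05
        t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical_value(n, alpha) == pytest.approx(expected, abs=1e-12)


def test_significance_categories_follow_convention():
    assert significance_category(0.049) == "significant"
    assert significance_category(0.05) == "trend"
    assert significance_category(0.0999) == "trend"
    assert significance_category(0.1) == "ns"
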