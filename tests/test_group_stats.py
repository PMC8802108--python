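"""Group statistics: identities, oracles and cross-checks.

pingouin (an independent implementation) serves as the oracle for Welch ANOVA
and Games-Howell; exhaustive rank computation for Kruskal-Wallis.
"""

import numpy as np
import pytest
from scipy import stats

from cardiobeat.errors import DegenerateDataError, InputError
from cardiobeat.group_stats import (
    brown_forsythe_anova,
    dose_trend_regression,
    games_howell,
    kruskal_wallis,
    one_way_anova,
    screen_outliers,
    welch_anova,
)


@pytest.fixture(scope="module")
def three_groups(rng=None):
    r = np.random.default_rng(77)
    return {
        "ctrl": r.normal(1.0, 0.1, 9),
        "low": r.normal(1.2, 0.25, 14),
        "high": r.normal(1.5, 0.05, 7),
    }


class TestOutlierScreen:
    def test_tight_cluster_unflagged(self, rng):
        res = screen_outliers(rng.normal(1.0, 0.01, 20))
        assert res.flagged_indices.size == 0

    def test_gross_outlier_flagged_exactly(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.01, 20), [10.0]])
        res = screen_outliers(x)
        assert res.flagged_indices.tolist() == [20]
        # brute-force check: the flagged point has the largest robust residual
        resid = np.abs(x - np.median(x))
        assert np.argmax(resid) == 20

    def test_identical_values_unflagged(self):
        res = screen_outliers(np.full(10, 3.0))
        assert res.flagged_indices.size == 0

    def test_small_n_skipped_with_all_kept(self):
        res = screen_outliers([1.0, 2.0])
        assert res.kept.size == 2 and res.flagged_indices.size == 0


class TestWelchFamily:
    def test_two_equal_groups_welch_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        res = welch_anova({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_welch_reduces_to_classical_f_for_two_balanced_groups(self):
        # k=2, equal sizes and variances: the Welch correction term vanishes
        # and Welch F equals the classical pooled F exactly.  (For k > 2 the
        # denominator correction is > 1 at any finite n, so equality is only
        # asymptotic.)
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        groups = {"a": base + 0.0, "b": base + 1.0}
        w = welch_anova(groups)
        f = one_way_anova(groups)
        assert w.statistic == pytest.approx(f.statistic, abs=1e-10)

    def test_welch_matches_pingouin(self, three_groups):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(
            [(g, v) for g, vals in three_groups.items() for v in vals],
            columns=["group", "value"],
        )
        ref = pg.welch_anova(data=df, dv="value", between="group")
        res = welch_anova(three_groups)
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.df[1] == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_brown_forsythe_statistic_form(self, three_groups):
        # independent recomputation of F* from first principles
        arrays = list(three_groups.values())
        n = np.array([len(a) for a in arrays])
        m = np.array([a.mean() for a in arrays])
        v = np.array([a.var(ddof=1) for a in arrays])
        grand = np.sum(n * m) / n.sum()
        f_star = np.sum(n * (m - grand) ** 2) / np.sum((1 - n / n.sum()) * v)
        assert brown_forsythe_anova(three_groups).statistic == pytest.approx(
            f_star, rel=1e-12
        )

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_anova({"a": np.ones(5), "b": np.ones(5)})


class TestGamesHowell:
    def test_identical_groups_adjusted_p_near_one(self, rng):
        x = rng.normal(0, 1, 15)
        res = games_howell({"a": x, "b": x + rng.normal(0, 1e-6, 15)})
        assert res.pairwise[0].p_value > 0.99

    def test_two_groups_matches_welch_via_q_mapping(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        res = games_howell({"a": a, "b": b})
        t, df = stats.ttest_ind(a, b, equal_var=False)
        pair = res.pairwise[0]
        assert pair.statistic == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)
        assert pair.p_value == pytest.approx(
            float(stats.studentized_range.sf(abs(t) * np.sqrt(2), 2, pair.df)),
            rel=1e-9,
        )

    def test_matches_pingouin(self, three_groups):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(
            [(g, v) for g, vals in three_groups.items() for v in vals],
            columns=["group", "value"],
        )
        ref = pg.pairwise_gameshowell(data=df, dv="value", between="group")
        res = games_howell(three_groups)
        ours = {tuple(sorted((c.group_a, c.group_b))): c for c in res.pairwise}
        for _, row in ref.iterrows():
            c = ours[tuple(sorted((row["A"], row["B"])))]
            assert c.p_value == pytest.approx(float(row["pval"]), abs=1e-6)


class TestRankAndClassical:
    def test_identical_noiseless_groups_f_zero(self):
        base = np.array([1.0, 2.0, 3.0])
        res = one_way_anova({"a": base, "b": base.copy()})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_two_groups_equals_ranksum_mapping(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        res = kruskal_wallis({"a": a, "b": b})
        ref = stats.kruskal(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        # k=2: H equals the squared standardized Wilcoxon rank-sum statistic
        z = stats.ranksums(a, b).statistic
        assert res.statistic == pytest.approx(z**2, rel=1e-6)

    def test_h_statistic_against_exhaustive_ranks(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
        allv = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(allv)
        n = allv.size
        idx = 0
        h = 0.0
        for vals in groups.values():
            r = ranks[idx: idx + len(vals)]
            h += r.sum() ** 2 / len(vals)
            idx += len(vals)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        assert kruskal_wallis(groups).statistic == pytest.approx(h, rel=1e-12)


class TestDoseTrend:
    def test_exact_line(self):
        conc = np.array([1e-6, 1e-5, 1e-4, 1e-3])
        y = 2 * np.log10(conc) + 1
        res = dose_trend_regression(conc, y)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        conc = np.repeat([1e-5, 1e-4, 1e-3, 1e-2], 3)
        y = rng.normal(1, 0.1, conc.size)
        perm = rng.permutation(conc.size)
        a = dose_trend_regression(conc, y)
        b = dose_trend_regression(conc[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.slope_p_value == pytest.approx(b.slope_p_value)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(InputError):
            dose_trend_regression([1e-5, 1e-4], [1.0, 1.1])


class TestLocationShiftInvariance:
    @pytest.mark.parametrize("test", [welch_anova, brown_forsythe_anova,
                                      one_way_anova, kruskal_wallis])
    def test_statistics_invariant_to_location_shift(self, test, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 10) for i in range(3)}
        shifted = {k: v + 100.0 for k, v in groups.items()}
        assert test(groups).statistic == pytest.approx(
            test(shifted).statistic, rel=1e-8
        )
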