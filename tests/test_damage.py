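"""Conductivity/RWC arithmetic, ranked Welch ANOVA, Games-Howell, CFU tests."""

import math

import numpy as np
import pytest
from scipy import stats

from rhizomarker.damage import (
    RwcMeasurement,
    cfu_ttest,
    compute_rwc,
    games_howell,
    relative_conductivity,
    welch_anova_ranked,
)
from rhizomarker.diversity import summary_ttest
from rhizomarker.errors import ValidationError
from rhizomarker.synthetic import generate_leakage_data


def welch_anova_oracle(groups):
    """Direct Welch (1951) formulas, independent of the implementation."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    w = n / s2
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3.0 / (k**2 - 1) * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    f = a / (1 + 2 * (k - 2) / 3 * lam)
    df2 = 1 / lam
    return f, k - 1, df2, stats.f.sf(f, k - 1, df2)


def studentized_range_sf_quadrature(q, k, df):
    """Tail probability of the studentized range by nested quadrature."""
    from scipy.integrate import quad

    def inner(w):
        val, _ = quad(
            lambda z: k * stats.norm.pdf(z)
            * (stats.norm.cdf(z) - stats.norm.cdf(z - w)) ** (k - 1),
            -8, 8, epsabs=1e-10, limit=200,
        )
        return val

    def outer(s):
        c = df ** (df / 2) / (math.gamma(df / 2) * 2 ** (df / 2 - 1))
        return c * s ** (df - 1) * math.exp(-df * s * s / 2) * inner(q * s)

    cdf, _ = quad(outer, 1e-8, 8, epsabs=1e-9, limit=200)
    return 1 - cdf


class TestConductivityRwc:
    @pytest.mark.parametrize("value,expected", [(2.0, 100.0), (0.0, 0.0), (0.5, 25.0)])
    def test_relative_conductivity(self, value, expected):
        assert relative_conductivity(value, 2.0) == pytest.approx(expected)

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            relative_conductivity(-1.0, 2.0)

    @pytest.mark.parametrize(
        "w,dw,sw,expected", [(5.0, 5.0, 10.0, 0.0), (10.0, 5.0, 10.0, 1.0),
                             (9.0, 5.0, 10.0, 0.8)]
    )
    def test_rwc(self, w, dw, sw, expected):
        assert compute_rwc(RwcMeasurement(w, dw, sw)) == pytest.approx(expected)

    def test_rwc_invalid_ordering_rejected(self):
        with pytest.raises(ValidationError):
            RwcMeasurement(11.0, 5.0, 10.0)


class TestWelchAnovaRanked:
    def test_identical_groups_null(self):
        groups = {"a": np.ones(4), "b": np.ones(4)}
        f, df1, df2, p = welch_anova_ranked(groups)
        assert f == 0.0 and p == 1.0

    def test_matches_direct_formula(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        f, df1, df2, p = welch_anova_ranked(groups)
        # ranks of 1..9 equal the data here
        f_o, df1_o, df2_o, p_o = welch_anova_oracle(
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        )
        assert f == pytest.approx(f_o, abs=1e-10)
        assert df2 == pytest.approx(df2_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_oracle_equivalence_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            groups = {
                f"g{i}": rng.normal(rng.normal(), rng.uniform(0.5, 3), rng.integers(3, 8))
                for i in range(rng.integers(2, 5))
            }
            f, _, df2, p = welch_anova_ranked(groups)
            pooled = np.concatenate(list(groups.values()))
            ranks = stats.rankdata(pooled)
            split = np.cumsum([len(v) for v in groups.values()])[:-1]
            f_o, _, df2_o, p_o = welch_anova_oracle(np.split(ranks, split))
            assert abs(f - f_o) < 1e-10 and abs(p - p_o) < 1e-10

    def test_matches_pingouin_on_ranks(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        values = {f"g{i}": rng.normal(i, 1 + i, 6) for i in range(3)}
        f, df1, df2, p = welch_anova_ranked(values)
        pooled = np.concatenate(list(values.values()))
        ranks = stats.rankdata(pooled)
        df = pd.DataFrame({
            "y": ranks,
            "g": np.repeat(list(values), [len(v) for v in values.values()]),
        })
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.gamma(2, 2, 5) for i in range(3)}
        f1, *_, p1 = welch_anova_ranked(groups)
        transformed = {k: np.exp(v / 3.0) for k, v in groups.items()}
        f2, *_, p2 = welch_anova_ranked(transformed)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_type_one_error_calibrated_under_heteroscedasticity(self):
        """Design case: unequal variances, alpha 0.05 within [0.03, 0.07].

        Checked at n >= 6 per group with a 1:2:3 spread of sds; at very small
        n (4 per group) combined with extreme variance ratios the rank +
        Welch combination is known to run liberal (documented limitation).
        """
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {
                "a": rng.normal(0, 1, 6),
                "b": rng.normal(0, 2, 6),
                "c": rng.normal(0, 3, 8),
            }
            *_, p = welch_anova_ranked(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestGamesHowell:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0, 1, 6)
        res = games_howell({"a": g, "b": g.copy()})
        assert res.pairs[0][5] > 0.99
        assert res.letters["a"] == res.letters["b"]

    def test_two_groups_equal_welch_t_transform(self):
        """k = 2: the GH p is the studentized-range transform of Welch's t."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(3, 8))
            b = rng.normal(rng.normal(), 2, rng.integers(3, 8))
            res = games_howell({"a": a, "b": b})
            _, _, q, df, p = res.pairs[0][1:]
            t_res = stats.ttest_ind(a, b, equal_var=False)
            assert q == pytest.approx(abs(t_res.statistic) * math.sqrt(2), abs=1e-10)
            assert p == pytest.approx(float(t_res.pvalue), abs=1e-6)

    def test_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            groups = {f"g{i}": rng.normal(i * 0.8, 1 + i, 5) for i in range(3)}
            res = games_howell(groups)
            for (_, _, _, q, df, p) in res.pairs:
                assert p == pytest.approx(
                    studentized_range_sf_quadrature(q, 3, df), abs=1e-6
                )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        values = {f"g{i}": rng.normal(i, 1 + 0.5 * i, 6) for i in range(3)}
        res = games_howell(values)
        df = pd.DataFrame({
            "y": np.concatenate(list(values.values())),
            "g": np.repeat(list(values), 6),
        })
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for (a, b, diff, q, dfp, p) in res.pairs:
            row = ref[(ref.A == a) & (ref.B == b)].iloc[0]
            assert p == pytest.approx(float(row["pval"]), abs=1e-6)

    def test_letter_display_chain_pattern(self):
        # constructed: only the extreme pair differs at alpha 0.05
        groups = {
            "A": np.array([1.0, 1.2, 0.8, 1.1]),
            "B": np.array([1.8, 3.0, 1.2, 2.6]),
            "C": np.array([3.3, 3.5, 3.1, 3.4]),
        }
        res = games_howell(groups)
        sig = {frozenset((a, b)) for a, b, *_, p in res.pairs if p < 0.05}
        assert sig == {frozenset(("A", "C"))}
        assert res.letters == {"A": "a", "B": "ab", "C": "b"}

    def test_letters_reproduce_significance_pattern(self):
        """Groups share a letter iff their pairwise p >= alpha."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 4), rng.uniform(0.5, 2), 5)
                for i in range(4)
            }
            res = games_howell(groups)
            for a, b, *_, p in res.pairs:
                share = set(res.letters[a]) & set(res.letters[b])
                assert bool(share) == (p >= res.alpha)


class TestCfuTtest:
    def test_identical_samples(self):
        t, _, p = cfu_ttest([1e6, 1e6], [1e6, 1e6])
        assert (t, p) == (0.0, 1.0)

    def test_large_difference_significant(self):
        t, df, p = cfu_ttest([1e6, 1.1e6, 0.9e6], [1e4, 1.2e4, 0.8e4])
        assert p < 0.05

    def test_consistent_with_summary_ttest(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(10, 2, 5), rng.normal(8, 1, 4)
        t1, df1, p1 = cfu_ttest(a, b)
        t2, df2, p2 = summary_ttest(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_log_transform_rejects_zero(self):
        with pytest.raises(ValidationError, match="pseudo-count"):
            cfu_ttest([0.0, 1e4], [1e4, 2e4], log_transform=True)


def test_leakage_pipeline_detects_wounding():
    """Wounded tissue at 60% vs intact ~8%: ranked Welch ANOVA rejects."""
    exp = generate_leakage_data(
        {"-ctrl": 8.0, "0% MeOH": 8.5, "50% MeOH": 9.0, "95% MeOH": 10.0,
         "wounded": 60.0},
        cv=0.25, n=4, seed=17,
    )
    groups = {
        k: np.array([relative_conductivity(v, exp.lysis_max) for v in vals])
        for k, vals in exp.groups.items()
    }
    f, df1, df2, p = welch_anova_ranked(groups)
    assert p < 0.01
    letters = games_howell(groups).letters
    assert letters["wounded"] not in {letters[k] for k in groups if k != "wounded"}
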