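"""OTU filtering, alpha diversity, rarefaction, distances, PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from rhizomarker.diversity import (
    OtuFilterParams,
    OtuTable,
    bray_curtis,
    permanova,
    prevalence_filter,
    rarefaction_curve,
    richness,
    shannon,
    summary_ttest,
)
from rhizomarker.errors import ValidationError
from rhizomarker.synthetic import generate_otu_table


def otu_table(counts, groups):
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"OTU{i}" for i in range(len(counts))],
        columns=[f"s{i}" for i in range(len(groups))],
    )
    return OtuTable(counts, pd.Series(list(groups), index=counts.columns))


class TestPrevalenceFilter:
    def test_rule_arithmetic(self):
        # 10 samples; kept: count 6 in 3 samples (3/10 >= 0.30) and total 21 > 20
        kept_row = [6, 6, 6, 3, 0, 0, 0, 0, 0, 0]
        # removed: prevalence 2/10 < 0.30 despite total 24
        low_prev = [6, 18, 0, 0, 0, 0, 0, 0, 0, 0]
        # removed: total exactly 20 (strict >)
        low_total = [6, 6, 6, 2, 0, 0, 0, 0, 0, 0]
        zero = [0] * 10
        table = otu_table([kept_row, low_prev, low_total, zero],
                          ["root_rhizosphere"] * 5 + ["control_soil"] * 5)
        out = prevalence_filter(table)
        assert list(out.counts.index) == ["OTU0"]

    def test_boundary_count_is_strict(self):
        # counts of exactly 5 never satisfy "> 5"
        row = [5] * 10
        table = otu_table([row], ["root_rhizosphere"] * 5 + ["control_soil"] * 5)
        assert len(prevalence_filter(table).counts) == 0

    def test_idempotent_and_subset(self):
        table, _ = generate_otu_table(200, 4, 3000, 0, 1.0, seed=3)
        once = prevalence_filter(table)
        twice = prevalence_filter(once)
        assert set(once.counts.index) <= set(table.counts.index)
        assert once.counts.equals(twice.counts)


class TestAlphaDiversity:
    def test_shannon_uniform_four(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_single_otu_zero(self):
        assert shannon([0, 9, 0]) == 0.0

    def test_shannon_hand_value(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_log2_option(self):
        assert shannon([5, 5, 5, 5], base="2") == pytest.approx(2.0, abs=1e-12)

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_uniform_maximizes_shannon(self, counts):
        h = shannon(counts)
        assert h <= shannon([1] * len(counts)) + 1e-12

    def test_richness(self):
        assert richness([0, 3, 5]) == 2
        assert richness([0, 0]) == 0


class TestRarefaction:
    COUNTS = [40, 25, 10, 5, 1, 0]

    def test_depth_one_gives_richness_one(self):
        curve = rarefaction_curve(self.COUNTS, [1], reps=50, seed=0)
        assert curve["mean_richness"].iloc[0] == 1.0

    def test_full_depth_recovers_observed_richness(self):
        total = sum(self.COUNTS)
        curve = rarefaction_curve(self.COUNTS, [total], reps=10, seed=0)
        assert curve["mean_richness"].iloc[0] == richness(self.COUNTS)
        assert curve["sd_richness"].iloc[0] == 0.0

    def test_mean_richness_non_decreasing(self):
        curve = rarefaction_curve(self.COUNTS, [5, 20, 50, 81], reps=500, seed=1)
        assert (np.diff(curve["mean_richness"]) > -0.2).all()

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValidationError):
            rarefaction_curve(self.COUNTS, [1000], reps=5, seed=0)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = otu_table([[3, 3], [7, 7]], ["root_rhizosphere", "control_soil"])
        d = bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_samples_one(self):
        t = otu_table([[5, 0], [0, 8]], ["root_rhizosphere", "control_soil"])
        assert bray_curtis(t).iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        t = otu_table([[2, 1], [0, 1]], ["root_rhizosphere", "control_soil"])
        assert bray_curtis(t).iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scipy(self):
        table, _ = generate_otu_table(50, 3, 2000, 0, 1.0, seed=5)
        d = bray_curtis(table)
        x = table.counts.to_numpy(dtype=float)
        for i in range(x.shape[1]):
            for j in range(i + 1, x.shape[1]):
                assert d.iloc[i, j] == pytest.approx(
                    scipy_braycurtis(x[:, i], x[:, j]), abs=1e-12
                )


class TestPermanova:
    def test_pseudo_f_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        table, _ = generate_otu_table(100, 4, 3000, 20, 5.0, seed=2)
        d = bray_curtis(table)
        mine = permanova(d, table.groups.loc[d.index], n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ref = skbio_stats.permanova(dm, table.groups.loc[d.index].to_numpy(),
                                    permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_power_on_separated_clusters(self):
        table, _ = generate_otu_table(200, 4, 5000, 40, 8.0, seed=4)
        d = bray_curtis(table)
        res = permanova(d, table.groups.loc[d.index], n_perm=999, seed=4)
        assert res.p <= 0.05

    def test_consistent_relabeling_leaves_f_unchanged(self):
        table, _ = generate_otu_table(80, 4, 2000, 10, 3.0, seed=6)
        d = bray_curtis(table).to_numpy()
        groups = table.groups.to_numpy()
        f1 = permanova(d, groups, n_perm=9, seed=0).pseudo_f
        perm = np.random.default_rng(1).permutation(len(groups))
        f2 = permanova(d[np.ix_(perm, perm)], groups[perm], n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            permanova(d, ["a", "a", "b"], n_perm=9)


class TestSummaryTtest:
    def test_equal_means_trivial(self):
        t, df, p = summary_ttest(5.0, 1.0, 4, 5.0, 1.0, 4)
        assert (t, p) == (0.0, 1.0)

    def test_pooled_hand_value(self):
        t, df, p = summary_ttest(10.0, 1.0, 4, 12.0, 1.0, 4)
        assert t == pytest.approx(-2.828, abs=1e-3)
        assert df == 6

    def test_welch_df_never_exceeds_pooled(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(2, 10, 2)
            sd1, sd2 = rng.uniform(0.1, 5, 2)
            _, df_w, _ = summary_ttest(0, sd1, n1, 1, sd2, n2, "welch")
            _, df_p, _ = summary_ttest(0, sd1, n1, 1, sd2, n2, "pooled")
            assert df_w <= df_p + 1e-9

    def test_degenerate_equal_zero_sd(self):
        t, _, p = summary_ttest(3.0, 0.0, 4, 3.0, 0.0, 4)
        assert (t, p) == (0.0, 1.0)
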