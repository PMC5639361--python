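"""Volcano statistics, threshold selection, pooling and the BH funnel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhizomarker.enrichment import (
    SelectionParams,
    anova_bh_filter,
    bh_qvalues,
    pool_top_k,
    presence_overlap,
    select_enriched,
    welch_volcano,
)
from rhizomarker.errors import ValidationError
from rhizomarker.synthetic import SyntheticConfig, generate_feature_table

from .conftest import make_table


def welch_oracle(a, b):
    """Textbook Welch formulas, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelchVolcano:
    def test_identical_groups_degenerate(self):
        t = make_table([[4.0] * 8], ["plant"] * 5 + ["control"] * 3)
        res = welch_volcano(t)
        row = res.iloc[0]
        assert (row["t"], row["p"], row["log2fc"]) == (0.0, 1.0, 0.0)
        assert row["direction"] == "none"

    def test_log2fc_from_group_means(self):
        t = make_table([[4.0] * 5 + [2.0] * 3], ["plant"] * 5 + ["control"] * 3)
        res = welch_volcano(t)
        assert res["log2fc"].iloc[0] == pytest.approx(1.0)
        assert res["direction"].iloc[0] == "plant"

    def test_matches_textbook_formula(self):
        plant = [10.2, 11.1, 9.8, 10.5, 10.9]
        control = [5.1, 4.8, 5.3]
        t = make_table([plant + control], ["plant"] * 5 + ["control"] * 3)
        res = welch_volcano(t).iloc[0]
        t_o, df_o, p_o = welch_oracle(plant, control)
        assert res["t"] == pytest.approx(t_o, abs=1e-10)
        assert res["df"] == pytest.approx(df_o, abs=1e-10)
        assert res["p"] == pytest.approx(p_o, abs=1e-10)

    def test_oracle_equivalence_many_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
            a = rng.normal(100, 2, n1)
            b = rng.normal(100 + rng.normal(), 3, n2)
            t = make_table([np.r_[a, b]], ["plant"] * n1 + ["control"] * n2)
            res = welch_volcano(t).iloc[0]
            t_o, df_o, p_o = welch_oracle(a, b)
            assert abs(res["t"] - t_o) < 1e-10
            assert abs(res["df"] - df_o) < 1e-10
            assert abs(res["p"] - p_o) < 1e-10

    def test_single_replicate_group_rejected(self):
        t = make_table([[1.0, 2.0, 3.0]], ["plant", "plant", "control"])
        with pytest.raises(ValidationError):
            welch_volcano(t)


class TestSelectEnriched:
    PARAMS = SelectionParams()

    def frame(self, p, log2fc):
        return pd.DataFrame({"log2fc": [log2fc], "p": [p]}, index=["ion"])

    def test_passing_ion_is_plant_enriched(self):
        plant, control = select_enriched(self.frame(0.005, 1.5), self.PARAMS)
        assert plant == {"ion"} and not control

    def test_thresholds_are_strict(self):
        plant, _ = select_enriched(self.frame(0.01, 1.5), self.PARAMS)
        assert not plant
        plant, _ = select_enriched(self.frame(0.005, 1.0), self.PARAMS)
        assert not plant

    def test_control_direction_symmetric(self):
        _, control = select_enriched(self.frame(0.005, -1.5), self.PARAMS)
        assert control == {"ion"}


class TestPresenceOverlap:
    def test_hand_built_partition(self):
        # 2 plant-only, 1 control-only, 3 shared by construction
        x = np.array(
            [
                [5.0, 0.0, 0.0],  # plant only
                [np.nan, 3.0, 0.0],  # plant only
                [0.0, 0.0, 7.0],  # control only
                [1.0, 1.0, 1.0],
                [2.0, 0.0, 2.0],
                [0.0, 4.0, 4.0],
            ]
        )
        t = make_table(x, ["plant", "plant", "control"])
        counts = presence_overlap(t)
        assert (counts["plant_only"], counts["control_only"], counts["shared"]) == (2, 1, 3)
        assert counts["total_detected"] == 6
        assert counts["pct_shared"] == pytest.approx(50.0)


class TestPoolTopK:
    def make_volcano(self, n, seed, prefix):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "log2fc": rng.uniform(1.5, 4, n),
                "p": rng.uniform(1e-8, 5e-3, n),
            },
            index=pd.Index([f"{prefix}{i}" for i in range(n)], name="feature_id"),
        )

    def test_six_plots_give_exactly_120(self):
        plots = [(f"m:{i}", self.make_volcano(40, i, f"p{i}_")) for i in range(6)]
        pooled = pool_top_k(plots, SelectionParams(top_k=20), "plant")
        assert len(pooled) == 120
        assert pooled.groupby("plot_id").size().eq(20).all()

    def test_shortfall_keeps_all_and_warns(self, caplog):
        plots = [("m:0", self.make_volcano(7, 0, "q"))]
        with caplog.at_level("WARNING"):
            pooled = pool_top_k(plots, SelectionParams(top_k=20), "plant")
        assert len(pooled) == 7
        assert "only 7" in caplog.text

    def test_tie_break_by_fold_change_then_id(self):
        df = pd.DataFrame(
            {"log2fc": [2.0, 3.0, 3.0], "p": [1e-4, 1e-4, 1e-4]},
            index=pd.Index(["c", "b", "a"], name="feature_id"),
        )
        pooled = pool_top_k([("m:0", df)], SelectionParams(top_k=3), "plant")
        assert list(pooled["feature_id"]) == ["a", "b", "c"]

    def test_duplicate_ids_across_plots_stay_distinct(self):
        df = self.make_volcano(25, 1, "x")
        pooled = pool_top_k([("m:0", df), ("m:1", df)], SelectionParams(top_k=20), "plant")
        assert len(pooled) == 40

    def test_empty_plot_list_rejected(self):
        with pytest.raises(ValidationError):
            pool_top_k([], SelectionParams(), "plant")


class TestBhRefinement:
    def test_bh_hand_example(self):
        q = bh_qvalues([0.001, 0.008, 0.039])
        np.testing.assert_allclose(q, [0.003, 0.012, 0.039], atol=1e-12)
        assert list(q < 0.01) == [True, False, False]

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_bh_monotone_in_sorted_p(self, pvals):
        q = bh_qvalues(sorted(pvals))
        assert (np.diff(q) >= -1e-12).all()

    def test_anova_filter_keeps_true_effects(self):
        config = SyntheticConfig(n_features_per_mode=300, seed=21, missing_rate=0.0)
        tables = {}
        plots = []
        parts = []
        for solution in (0, 50, 95):
            t, truth = generate_feature_table(config, solution, "positive")
            parts.append(t)
            plots.append((f"positive:{solution}", welch_volcano(t)))
        features = parts[0].features
        samples = pd.concat([p.samples for p in parts])
        matrix = np.concatenate([p.intensities for p in parts], axis=1)
        from rhizomarker.dataio import FeatureTable

        tables["positive"] = FeatureTable(features.copy(), samples, matrix)
        pooled = pool_top_k(plots, SelectionParams(top_k=20), "plant")
        refined = anova_bh_filter(pooled, tables, alpha=0.01)
        assert refined["kept"].mean() > 0.9  # strong spiked effects survive
        assert (refined.loc[refined["kept"], "bh_q"] < 0.01).all()

    def test_uniform_tiny_p_all_kept(self):
        q = bh_qvalues([1e-6] * 10)
        assert (q < 0.01).all()
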