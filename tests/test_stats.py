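"""Statistical harness: RMSE, gating, one-way and two-way branches."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stridevar.stats import (
    evaluate_strategies,
    holm_adjust,
    normality_gate,
    one_way_compare,
    rmse,
    two_way_compare,
    welch_anova_f,
)
from stridevar.stats import _dunn, _games_howell

from _oracles import kruskal_reference


class TestRMSE:
    def test_identical_sequences_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_arithmetic_example(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 40)
        assert rmse(a, b) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestHolm:
    def test_monotone_and_never_below_raw(self):
        p = np.random.default_rng(1).uniform(size=9)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_single_comparison_unchanged(self):
        assert holm_adjust([0.031])[0] == pytest.approx(0.031)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(2).uniform(size=7)
        np.testing.assert_allclose(holm_adjust(p), multipletests(p, method="holm")[1])


class TestNormalityGate:
    def test_normal_groups_go_parametric(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            groups = [rng.standard_normal(50) for _ in range(3)]
            hits += normality_gate(groups) == "parametric"
        assert hits >= 18  # >= 90 % of draws

    def test_skewed_groups_go_nonparametric(self):
        rng = np.random.default_rng(0)
        groups = [rng.exponential(size=50) for _ in range(3)]
        assert normality_gate(groups) == "nonparametric"

    def test_majority_rule(self):
        rng = np.random.default_rng(3)
        skewed = [rng.exponential(size=60) ** 2 for _ in range(2)]
        normal = [rng.standard_normal(60)]
        assert normality_gate(skewed + normal) == "nonparametric"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([np.array([1.0, 2.0])])


class TestOneWay:
    def test_welch_f_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 20), rng.normal(0.4, 2, 25), rng.normal(1, 1, 15)]
        f, df1, df2, p = welch_anova_f(groups)
        frame = pd.DataFrame(
            {"v": np.concatenate(groups), "g": np.repeat([0, 1, 2], [20, 25, 15])}
        )
        ref = pg.welch_anova(dv="v", between="g", data=frame)
        assert f == pytest.approx(ref["F"][0], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"][0], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"][0], rel=1e-9)

    def test_welch_f_equals_squared_welch_t_for_two_groups(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 18)
        f = welch_anova_f([a, b])[0]
        t = sps.ttest_ind(a, b, equal_var=False).statistic
        assert f == pytest.approx(t**2, rel=1e-9)

    def test_games_howell_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 2, 25), rng.normal(1, 1, 15)]
        mine = _games_howell(groups, ["a", "b", "c"])
        frame = pd.DataFrame(
            {"v": np.concatenate(groups), "g": np.repeat([0, 1, 2], [20, 25, 15])}
        )
        ref = pg.pairwise_gameshowell(dv="v", between="g", data=frame)
        np.testing.assert_allclose(mine["p_raw"], ref["pval"], atol=1e-8)

    def test_kruskal_matches_hand_computation(self):
        groups = [
            np.array([2.1, 3.5, 1.2, 4.4]),
            np.array([5.0, 6.1, 5.5, 7.2]),
            np.array([1.1, 2.2, 3.3, 2.5]),
        ]
        h_scipy = sps.kruskal(*groups).statistic
        assert kruskal_reference(groups) == pytest.approx(h_scipy, abs=1e-10)
        res = one_way_compare(groups, posthoc="never", effect_ci=False)
        if res.branch == "nonparametric":
            assert res.statistic == pytest.approx(h_scipy, abs=1e-10)

    def test_dunn_z_matches_direct_formula(self):
        groups = [np.array([1.0, 2, 3, 4]), np.array([2.5, 3.5, 4.5, 5.5]),
                  np.array([5.0, 6, 7, 8])]
        out = _dunn(groups, ["a", "b", "c"])
        # direct recomputation for the (a, c) pair, no ties
        all_vals = np.concatenate(groups)
        ranks = sps.rankdata(all_vals)
        n = len(all_vals)
        ra, rc = ranks[:4].mean(), ranks[8:].mean()
        z = (ra - rc) / np.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 4))
        row = out[(out["group_a"] == "a") & (out["group_b"] == "c")].iloc[0]
        assert row["statistic"] == pytest.approx(z, abs=1e-10)

    def test_degenerate_constant_groups_flagged(self):
        res = one_way_compare([np.full(5, 2.0), np.full(5, 2.0)])
        assert res.degenerate and res.p_value == 1.0

    def test_effect_size_ci_contains_point(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.8, 1, 25) for i in range(3)]
        res = one_way_compare(groups, effect_ci=True, seed=1)
        lo, hi = res.effect_ci
        assert lo <= res.effect_size <= hi


class TestTwoWay:
    @staticmethod
    def _frame(seed, a_shift=0.0, b_shift=0.0, inter=0.0, n=12):
        rng = np.random.default_rng(seed)
        rows = []
        for i, a in enumerate(["c1", "c2", "c3"]):
            for j, b in enumerate(["s1", "s2"]):
                for _ in range(n):
                    val = rng.standard_normal() + a_shift * i + b_shift * j
                    if i == 2 and j == 1:
                        val += inter
                    rows.append({"condition": a, "strategy": b, "value": val})
        return pd.DataFrame(rows)

    def test_additive_effects_detected_interaction_not(self):
        """Strong additive shifts: main effects significant, interaction not."""
        hits = {"factor_a": 0, "factor_b": 0, "interaction": 0}
        for s in range(10):
            res = two_way_compare(self._frame(s, a_shift=1.5, b_shift=1.2))
            p = res.parametric["PR(>F)"]
            hits["factor_a"] += p["factor_a"] < 0.05
            hits["factor_b"] += p["factor_b"] < 0.05
            hits["interaction"] += p["interaction"] < 0.05
        assert hits["factor_a"] == 10 and hits["factor_b"] == 10
        assert hits["interaction"] <= 3

    def test_permuting_strategy_labels_destroys_strategy_effect(self):
        frame = self._frame(3, b_shift=2.0)
        res = two_way_compare(frame)
        assert res.parametric["PR(>F)"]["factor_b"] < 1e-6
        rng = np.random.default_rng(0)
        perm = frame.copy()
        for c in perm["condition"].unique():
            m = perm["condition"] == c
            perm.loc[m, "strategy"] = rng.permutation(perm.loc[m, "strategy"].to_numpy())
        res_p = two_way_compare(perm)
        assert res_p.parametric["PR(>F)"]["factor_b"] > 0.05

    def test_aligned_rank_table_reported_alongside(self):
        res = two_way_compare(self._frame(1, a_shift=1.0))
        assert set(res.nonparametric.index) == {"factor_a", "factor_b", "interaction"}
        assert res.parametric is not None

    def test_thin_cells_warn(self):
        frame = self._frame(2)
        frame = frame[~((frame["condition"] == "c3") & (frame["strategy"] == "s2"))]
        solo = pd.DataFrame([{"condition": "c3", "strategy": "s2", "value": 0.0}])
        res = two_way_compare(pd.concat([frame, solo]))
        assert res.warnings


class TestEvaluateStrategies:
    @staticmethod
    def _table(seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for runner in [f"R{i}" for i in range(8)]:
            for cond in ["a", "b", "c"]:
                ref = 1.4 + 0.05 * rng.standard_normal()
                rows.append(dict(runner=runner, condition=cond, variable="SF",
                                 strategy="reference", unit=-1, value=ref))
                rows.append(dict(runner=runner, condition=cond, variable="SF",
                                 strategy="alt", unit=-1, value=ref + 0.01))
        return pd.DataFrame(rows)

    def test_reference_vs_itself_zero_rmse(self):
        table = self._table()
        clone = table.copy()
        clone.loc[clone["strategy"] == "alt", "value"] = clone.loc[
            clone["strategy"] == "reference", "value"
        ].to_numpy()
        out = evaluate_strategies(clone)
        assert np.allclose(out.rmse_rows["rmse"], 0.0)

    def test_constant_offset_reported_exactly(self):
        out = evaluate_strategies(self._table())
        assert np.allclose(out.rmse_rows["rmse"], 0.01)

    def test_removing_condition_removes_exactly_its_rows(self):
        table = self._table()
        full = evaluate_strategies(table)
        part = evaluate_strategies(table[table["condition"] != "b"])
        assert set(full.rmse_rows["condition"]) - set(part.rmse_rows["condition"]) == {"b"}
        assert len(part.rmse_rows) == len(full.rmse_rows) - 1
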