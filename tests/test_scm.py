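"""Demeaned SCM: demeaning, weight fitting, effects, and fit diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_panel
from scmdecomp.errors import MissingDataError
from scmdecomp.scm import (
    ScmWeights,
    compute_att,
    demean,
    fit_scm,
    fit_weights,
    overall_rmse,
    pre_rmse,
    solve_simplex_lsq,
)


def grid_simplex(k, step=1e-3):
    """Dense grid over the (k-1)-simplex; oracle for small weight problems."""
    if k == 2:
        w1 = np.arange(0, 1 + step / 2, step)
        return np.column_stack([w1, 1 - w1])
    if k == 3:
        w1, w2 = np.meshgrid(np.arange(0, 1 + step / 2, step), np.arange(0, 1 + step / 2, step))
        w1, w2 = w1.ravel(), w2.ravel()
        keep = w1 + w2 <= 1 + 1e-12
        return np.column_stack([w1[keep], w2[keep], 1 - w1[keep] - w2[keep]])
    raise ValueError(k)


class TestDemean:
    def test_constant_series_residuals_zero(self):
        panel = make_panel({"math": {"T": {2013: 2.0, 2014: 2.0, 2015: 2.0}}})
        out = demean(panel, "math", 2015)
        assert (out["resid"] == 0).all()

    def test_hand_arithmetic(self):
        panel = make_panel({"math": {"T": {2013: 1.0, 2014: 3.0, 2015: 5.0}}})
        out = demean(panel, "math", 2015).set_index("year")["resid"]
        assert list(out) == [-1.0, 1.0, 3.0]

    def test_pre_residuals_average_zero_per_unit(self, toy_panel):
        out = demean(toy_panel, "math", 2015)
        pre_means = out[out["period"] == "pre"].groupby("unit")["resid"].mean()
        np.testing.assert_allclose(pre_means, 0.0, atol=1e-12)

    def test_unit_without_pre_dropped_treated_fatal(self):
        panel = make_panel(
            {"math": {"T": {2014: 1.0, 2015: 2.0}, "A": {2015: 4.0}, "B": {2014: 0.0, 2015: 1.0}}}
        )
        with pytest.warns(UserWarning, match="no pretreatment"):
            out = demean(panel, "math", 2015)
        assert "A" not in set(out["unit"])
        bad = make_panel({"math": {"T": {2015: 2.0}, "B": {2014: 0.0, 2015: 1.0}}})
        with pytest.raises(MissingDataError):
            demean(bad, "math", 2015, treated_id="T")


class TestFitWeights:
    def test_perfect_match_control_gets_weight_one(self):
        panel = make_panel(
            {
                "math": {
                    "T": {2012: 1.0, 2013: 2.0, 2014: 3.0, 2015: 9.0},
                    # same demeaned pre trajectory as T, shifted level
                    "A": {2012: 6.0, 2013: 7.0, 2014: 8.0, 2015: 8.0},
                    "B": {2012: 2.0, 2013: 1.0, 2014: 3.0, 2015: 3.0},
                }
            }
        )
        w, obj, _ = fit_weights(panel, "T", ["A", "B"], ["math"], 2015)
        assert w.as_dict()["A"] == pytest.approx(1.0, abs=1e-6)
        assert obj == pytest.approx(0.0, abs=1e-10)

    def test_recovers_convex_combination(self):
        rng = np.random.default_rng(2)
        years = range(2008, 2016)
        a = {y: float(v) for y, v in zip(years, rng.normal(0, 1, 8))}
        b = {y: float(v) for y, v in zip(years, rng.normal(0, 1, 8))}
        t = {y: 0.3 * a[y] + 0.7 * b[y] for y in years}
        panel = make_panel({"math": {"T": t, "A": a, "B": b}})
        w, obj, _ = fit_weights(panel, "T", ["A", "B"], ["math"], 2015)
        assert w.as_dict()["A"] == pytest.approx(0.3, abs=1e-4)
        assert w.as_dict()["B"] == pytest.approx(0.7, abs=1e-4)

    def test_weights_live_on_simplex(self):
        rng = np.random.default_rng(3)
        panel = make_panel(
            {
                "math": {
                    u: {y: float(v) for y, v in zip(range(2010, 2017), rng.normal(0, 1, 7))}
                    for u in ["T", "A", "B", "C"]
                }
            }
        )
        w, _, _ = fit_weights(panel, "T", ["A", "B", "C"], ["math"], 2015)
        assert (w.values >= 0).all()
        assert w.values.sum() == pytest.approx(1.0, abs=1e-8)

    def test_single_control_gets_unit_weight(self):
        panel = make_panel(
            {"math": {"T": {2014: 1.0, 2015: 0.0}, "A": {2014: 5.0, 2015: 9.0}}}
        )
        w, _, _ = fit_weights(panel, "T", ["A"], ["math"], 2015)
        assert w.values.tolist() == [1.0]

    @pytest.mark.parametrize("n_controls", [2, 3])
    def test_matches_grid_search_oracle(self, n_controls):
        rng = np.random.default_rng(7 + n_controls)
        years = list(range(2009, 2017))
        series = {
            u: {y: float(v) for y, v in zip(years, rng.normal(0, 1, len(years)))}
            for u in ["T"] + [f"C{i}" for i in range(n_controls)]
        }
        panel = make_panel({"math": series})
        controls = [f"C{i}" for i in range(n_controls)]
        w, obj, scales = fit_weights(panel, "T", controls, ["math"], 2015)
        # independent oracle: demean by hand, scan a 1e-3 grid of the simplex
        wide = panel.pivot(index="year", columns="unit", values="value")
        pre = wide[wide.index < 2015]
        resid = pre - pre.mean(0)
        sd = np.std(pre.to_numpy())  # pooled pre SD over the analytic sample
        A = resid[controls].to_numpy() / sd
        b = resid["T"].to_numpy() / sd
        grid = grid_simplex(n_controls)
        objs = ((A @ grid.T - b[:, None]) ** 2).sum(axis=0)
        assert obj <= objs.min() + 2e-3


class TestComputeAtt:
    def test_null_when_treated_equals_synthetic(self):
        base = {2013: 1.0, 2014: 2.0, 2015: 3.0, 2016: 4.0}
        panel = make_panel(
            {"math": {"T": base, "A": {y: v + 1 for y, v in base.items()}}}
        )
        w = ScmWeights(("A",), np.array([1.0]))
        att, gaps, _ = compute_att(panel, w, "math", 2015, "T")
        assert att == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(gaps, 0.0, atol=1e-12)

    def test_toy_hand_arithmetic(self, toy_panel):
        # diffs: T 2.0, A 1.5, B 0.5; w=(0.5,0.5) -> ATT = 2.0 - 1.0 = 1.0
        w = ScmWeights(("A", "B"), np.array([0.5, 0.5]))
        att, gaps, _ = compute_att(toy_panel, w, "math", 2015, "T")
        assert att == pytest.approx(1.0, abs=1e-12)

    def test_att_equals_mean_post_gap_and_both_forms_agree(self, toy_panel):
        w = ScmWeights(("A", "B"), np.array([0.25, 0.75]))
        att, gaps, means = compute_att(toy_panel, w, "math", 2015, "T")
        post_gap_mean = gaps[gaps.index >= 2015].mean()
        assert att == pytest.approx(post_gap_mean, abs=1e-12)
        eq3 = (means["y_treated"] - means["x_treated"]) - (
            means["y_synthetic"] - means["x_synthetic"]
        )
        assert att == pytest.approx(eq3, abs=1e-14)

    def test_unit_level_shift_leaves_att_unchanged(self, toy_panel):
        w = ScmWeights(("A", "B"), np.array([0.6, 0.4]))
        att0, _, _ = compute_att(toy_panel, w, "math", 2015, "T")
        shifted = toy_panel.copy()
        shifted.loc[shifted["unit"] == "B", "value"] += 17.3
        att1, _, _ = compute_att(shifted, w, "math", 2015, "T")
        assert att1 == pytest.approx(att0, abs=1e-10)

    def test_common_year_shock_leaves_att_unchanged(self, toy_panel):
        w = ScmWeights(("A", "B"), np.array([0.6, 0.4]))
        att0, _, _ = compute_att(toy_panel, w, "math", 2015, "T")
        rng = np.random.default_rng(0)
        shocks = {y: rng.normal(0, 5) for y in toy_panel["year"].unique()}
        shocked = toy_panel.assign(
            value=toy_panel["value"] + toy_panel["year"].map(shocks)
        )
        att1, _, _ = compute_att(shocked, w, "math", 2015, "T")
        assert att1 == pytest.approx(att0, abs=1e-10)

    def test_missing_treated_post_raises(self):
        panel = make_panel({"math": {"T": {2014: 1.0}, "A": {2014: 0.0, 2015: 1.0}}})
        with pytest.raises(MissingDataError):
            compute_att(panel, ScmWeights(("A",), np.array([1.0])), "math", 2015, "T")

    def test_equals_weighted_two_period_did_regression(self, toy_panel):
        # independent route: WLS regression on (unit, period) cell means
        w = ScmWeights(("A", "B"), np.array([0.3, 0.7]))
        att, _, _ = compute_att(toy_panel, w, "math", 2015, "T")
        wide = toy_panel.pivot(index="year", columns="unit", values="value")
        rows = []
        for unit, weight in [("T", 1.0), ("A", 0.3), ("B", 0.7)]:
            rows.append((unit, 0, wide.loc[:2014, unit].mean(), weight))
            rows.append((unit, 1, wide.loc[2015:, unit].mean(), weight))
        df = pd.DataFrame(rows, columns=["unit", "post", "y", "w"])
        df["treated"] = (df["unit"] == "T").astype(float)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "post": df["post"],
                    "treated": df["treated"],
                    "did": df["post"] * df["treated"],
                }
            )
        )
        beta = sm.WLS(df["y"], X, weights=df["w"]).fit().params["did"]
        assert att == pytest.approx(beta, abs=1e-10)


class TestRmse:
    def test_zero_for_perfect_pre_fit(self):
        base = {2013: 1.0, 2014: 2.0, 2015: 9.0}
        panel = make_panel({"math": {"T": base, "A": {y: v - 3 for y, v in base.items()}}})
        w = ScmWeights(("A",), np.array([1.0]))
        assert pre_rmse(panel, w, "math", 2015, "T") == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_for_two_gaps(self):
        # pre gaps {0.03, -0.04} -> sqrt((9+16)/2)*1e-2
        panel = make_panel(
            {
                "math": {
                    "T": {2013: 0.03, 2014: -0.04, 2015: 1.0},
                    "A": {2013: 0.0, 2014: 0.0, 2015: 0.0},
                }
            }
        )
        # demeaning shifts both series; build gaps directly via a zero control
        w = ScmWeights(("A",), np.array([1.0]))
        t_demeaned_pre = np.array([0.03, -0.04]) - np.mean([0.03, -0.04])
        expected = np.sqrt(np.mean(t_demeaned_pre**2))
        assert pre_rmse(panel, w, "math", 2015, "T") == pytest.approx(expected, abs=1e-12)
        assert np.sqrt((0.03**2 + 0.04**2) / 2) == pytest.approx(0.0354, abs=5e-5)

    def test_overall_invariant_to_outcome_rescaling(self):
        rng = np.random.default_rng(4)
        years = list(range(2010, 2017))
        vals = {
            o: {
                u: {y: float(v) for y, v in zip(years, rng.normal(0, 1, len(years)))}
                for u in ["T", "A", "B"]
            }
            for o in ("math", "attendance")
        }
        panel = make_panel(vals)
        w = ScmWeights(("A", "B"), np.array([0.5, 0.5]))
        r0 = overall_rmse(panel, w, ["math", "attendance"], 2015, "T")
        scaled = panel.copy()
        scaled.loc[scaled["outcome"] == "attendance", "value"] *= 37.0
        r1 = overall_rmse(scaled, w, ["math", "attendance"], 2015, "T")
        assert r1 == pytest.approx(r0, abs=1e-10)


class TestFitScm:
    def test_full_subset_reproduces_fit_weights(self, toy_panel):
        fit = fit_scm(toy_panel, "T", ["A", "B"])
        w, obj, scales = fit_weights(toy_panel, "T", ["A", "B"], ["math"], 2015)
        np.testing.assert_array_equal(fit.weights.values, w.values)
        assert fit.objective == obj
        assert fit.scales == scales

    def test_single_outcome_perfect_control(self):
        base = {2012: 0.0, 2013: 1.0, 2014: -1.0, 2015: 5.0}
        panel = make_panel(
            {
                "math": {
                    "T": base,
                    "A": {y: v + 2 for y, v in base.items()},
                    "B": {2012: 1.0, 2013: 1.0, 2014: 1.0, 2015: 1.0},
                }
            }
        )
        fit = fit_scm(panel, "T", ["A", "B"], outcome_subset=["math"])
        assert fit.weights.as_dict()["A"] == pytest.approx(1.0, abs=1e-6)
        assert fit.pre_rmse["math"] == pytest.approx(0.0, abs=1e-8)

    def test_joint_fit_equals_manually_stacked_solve(self):
        rng = np.random.default_rng(9)
        years = list(range(2009, 2017))
        panel = make_panel(
            {
                o: {
                    u: {y: float(v) for y, v in zip(years, rng.normal(0, 1, len(years)))}
                    for u in ["T", "A", "B"]
                }
                for o in ("math", "reading")
            }
        )
        fit = fit_scm(panel, "T", ["A", "B"])
        # oracle: stack both outcomes by hand and scan the 1-simplex
        blocks_a, blocks_b = [], []
        for o in ("math", "reading"):
            wide = panel[panel["outcome"] == o].pivot(
                index="year", columns="unit", values="value"
            )
            pre = wide[wide.index < 2015]
            resid = pre - pre.mean(0)
            sd = np.std(pre.to_numpy())
            blocks_a.append(resid[["A", "B"]].to_numpy() / sd)
            blocks_b.append(resid["T"].to_numpy() / sd)
        A = np.vstack(blocks_a)
        b = np.concatenate(blocks_b)
        grid = grid_simplex(2, step=1e-4)
        objs = ((A @ grid.T - b[:, None]) ** 2).sum(axis=0)
        best = grid[np.argmin(objs)]
        assert fit.objective <= objs.min() + 1e-6
        assert fit.weights.as_dict()["A"] == pytest.approx(best[0], abs=1e-3)

    def test_weights_fitted_on_subset_effects_reported_for_all(self, toy_panel):
        two = pd.concat(
            [
                toy_panel,
                make_panel(
                    {
                        "reading": {
                            "T": {2013: 0.0, 2014: 0.1, 2015: 0.5, 2016: 0.2},
                            "A": {2013: 0.0, 2014: 0.0, 2015: 0.1, 2016: 0.1},
                            "B": {2013: 0.2, 2014: 0.1, 2015: 0.0, 2016: 0.3},
                        }
                    }
                ),
            ],
            ignore_index=True,
        )
        fit = fit_scm(two, "T", ["A", "B"], outcome_subset=["math"])
        assert fit.outcomes_fitted == ("math",)
        assert set(fit.att) == {"math", "reading"}

    def test_unknown_outcome_subset_raises(self, toy_panel):
        with pytest.raises(MissingDataError):
            fit_scm(toy_panel, "T", ["A", "B"], outcome_subset=["science"])


class TestSolver:
    def test_exact_interior_solution(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 3))
        b = A @ np.array([0.2, 0.3, 0.5])
        w, obj = solve_simplex_lsq(A, b)
        np.testing.assert_allclose(w, [0.2, 0.3, 0.5], atol=1e-8)

    def test_boundary_solution_nonnegative(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((12, 4))
        b = A @ np.array([1.4, -0.4, 0.0, 0.0])  # target outside the simplex
        w, obj = solve_simplex_lsq(A, b)
        assert (w >= 0).all() and w.sum() == pytest.approx(1.0, abs=1e-10)
        # KKT check: no feasible direction improves the objective
        G = A.T @ A
        grad = 2 * (G @ w - A.T @ b)
        mu = grad[w > 0].mean()
        assert (grad - mu >= -1e-7).all()

    def test_ridge_breaks_ties_toward_spread_weights(self):
        # two identical controls: any split is optimal; ridge picks 50/50
        A = np.column_stack([np.ones(5), np.ones(5)])
        b = np.ones(5)
        w, _ = solve_simplex_lsq(A, b)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)
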