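"""Uncertainty for synthetic-control effects.

Two tools live here.  The delete-one-control jackknife refits the whole
weight problem with each control district removed, so the resulting
standard errors reflect uncertainty created by the weight-selection process
as well as imperfect pretreatment fit.  The two-way fixed-effects (TWFE)
equality test stacks the two treated-unit subgroup series on top of the
weighted control panel and tests whether the post-treatment shift differs
between subgroups; because both subgroup effects are contrasts against the
same synthetic aggregate, the triple-interaction coefficient equals the
difference of the two subgroup ATTs exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MissingDataError, RankError, SolverError
from .scm import ScmWeights, fit_scm

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AttInference:
    """Jackknife SEs, 95% CIs, and the replicate estimates per outcome."""

    estimates: dict
    se: dict
    ci_low: dict
    ci_high: dict
    replicates: pd.DataFrame  # index: deleted control, columns: outcomes
    dropped_replicates: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            outcome: {
                "att": float(self.estimates[outcome]),
                "se": float(self.se[outcome]),
                "ci_low": float(self.ci_low[outcome]),
                "ci_high": float(self.ci_high[outcome]),
                "replicates": {
                    str(j): float(v) for j, v in self.replicates[outcome].items()
                },
            }
            for outcome in self.estimates
        }


def jackknife_se(
    panel: pd.DataFrame,
    treated_id,
    pool,
    outcome_subset=None,
    treatment_year: int = 2015,
    full_fit=None,
    **fit_kwargs,
) -> AttInference:
    """Delete-one-control jackknife over the donor pool.

    For each control j the weights and ATTs are refit (not merely
    renormalized) on the pool without j.  With N_c controls,

        SE^2 = (N_c - 1)/N_c * sum_j (ATT_(j) - mean_j ATT_(.))^2

    and the 95% CI is estimate +/- 1.96 SE.  Replicates whose solver fails
    are dropped with a warning and recorded.
    """
    from .scm import _wide, solve_simplex_lsq, stack_design

    pool = list(pool)
    if len(pool) < 3:
        raise MissingDataError("jackknife requires at least 3 control units")
    if full_fit is None:
        full_fit = fit_scm(
            panel, treated_id, pool, outcome_subset, treatment_year, **fit_kwargs
        )
    ridge = fit_kwargs.get("ridge", None)

    # per-outcome unscaled design blocks and pre-value moments, built once;
    # each replicate is a genuine refit (column deletion plus recomputed
    # per-outcome scaling SDs), not a renormalization of the full weights
    unit_scales = {o: 1.0 for o in full_fit.outcomes_fitted}
    blocks = {}  # outcome -> (A_block, b_block, pre-values year x unit array)
    diffs = {}  # outcome -> (treated post-pre diff, control diffs in pool order)
    for outcome in full_fit.outcomes_fitted:
        A_o, b_o, _ = stack_design(
            panel, treated_id, pool, [outcome], treatment_year, scales=unit_scales
        )
        wide = _wide(panel, outcome)[[treated_id] + pool]
        pre_vals = wide.loc[wide.index < treatment_year].to_numpy()
        blocks[outcome] = (A_o, b_o, pre_vals)
    for outcome in full_fit.outcomes:
        wide = _wide(panel, outcome)[[treated_id] + pool]
        x = wide.loc[wide.index < treatment_year].mean(axis=0)
        y = wide.loc[wide.index >= treatment_year].mean(axis=0)
        d = (y - x).to_numpy()
        diffs[outcome] = (float(d[0]), d[1:])

    rows, dropped = {}, []
    for pos, j in enumerate(pool):
        keep = [k for k in range(len(pool)) if k != pos]
        a_parts, b_parts = [], []
        for outcome in full_fit.outcomes_fitted:
            A_o, b_o, pre_vals = blocks[outcome]
            sd = float(np.nanstd(np.delete(pre_vals, pos + 1, axis=1), ddof=0))
            a_parts.append(A_o[:, keep] / sd)
            b_parts.append(b_o / sd)
        try:
            w_j, _ = solve_simplex_lsq(
                np.vstack(a_parts),
                np.concatenate(b_parts),
                **({} if ridge is None else {"ridge": ridge}),
            )
        except SolverError as exc:  # pragma: no cover - defensive
            warnings.warn(f"jackknife replicate without {j!r} failed: {exc}")
            dropped.append(j)
            continue
        rows[j] = {
            outcome: d1 - float(w_j @ dc[keep]) for outcome, (d1, dc) in diffs.items()
        }
    replicates = pd.DataFrame.from_dict(rows, orient="index")
    n = len(replicates)
    if n < 2:
        raise MissingDataError("too few successful jackknife replicates")

    se, lo, hi = {}, {}, {}
    for outcome in replicates.columns:
        reps = replicates[outcome].to_numpy(float)
        se_o = float(np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)))
        est = float(full_fit.att[outcome])
        se[outcome] = se_o
        lo[outcome] = est - Z_95 * se_o
        hi[outcome] = est + Z_95 * se_o
    return AttInference(
        estimates=dict(full_fit.att),
        se=se,
        ci_low=lo,
        ci_high=hi,
        replicates=replicates,
        dropped_replicates=dropped,
    )


@dataclass
class EqualityTest:
    """TWFE test of equal treatment effects across two subgroups."""

    estimate: float  # ATT(s=1) - ATT(s=0)
    se: float
    pvalue: float

    def to_dict(self) -> dict:
        return {"estimate": float(self.estimate), "se": float(self.se), "p": float(self.pvalue)}


def twfe_att_se(
    control_values: pd.DataFrame,
    weights: ScmWeights,
    series: pd.Series,
    treatment_year: int,
) -> tuple[float, float]:
    """Post-treatment shift of one treated series vs the weighted controls.

    A two-way fixed-effects regression of the stacked (series + weighted
    controls) data on unit effects, year effects, and a post-x-treated
    dummy.  The dummy's coefficient equals the series' ATT against the
    synthetic aggregate; its HC3 SE is the regression-based SE reported for
    subgroup effects (which ignores weight-selection uncertainty).
    """
    years = series.index.to_numpy()
    w_map = {i: w for i, w in zip(weights.control_ids, weights.values) if w > 0}
    ctrl = control_values[control_values["unit"].isin(w_map)].copy()
    ctrl["weight"] = ctrl["unit"].map(w_map)
    ctrl = ctrl[ctrl["year"].isin(years)]
    ctrl["post_treated"] = 0.0
    block = pd.DataFrame(
        {
            "unit": "__treated__",
            "year": years,
            "value": series.to_numpy(float),
            "weight": 1.0,
            "post_treated": (years >= treatment_year).astype(float),
        }
    )
    data = pd.concat(
        [ctrl[["unit", "year", "value", "weight", "post_treated"]], block],
        ignore_index=True,
    )
    unit_d = pd.get_dummies(data["unit"], prefix="u", drop_first=True, dtype=float)
    year_d = pd.get_dummies(data["year"], prefix="t", drop_first=True, dtype=float)
    X = pd.concat(
        [pd.Series(1.0, index=data.index, name="const"), unit_d, year_d, data[["post_treated"]]],
        axis=1,
    )
    Xw = X.to_numpy() * np.sqrt(data["weight"].to_numpy())[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise RankError("collinear TWFE design")
    fitted = sm.WLS(
        data["value"].to_numpy(float), X, weights=data["weight"].to_numpy()
    ).fit(cov_type="HC3")
    return float(fitted.params["post_treated"]), float(fitted.bse["post_treated"])


def twfe_equality_test(
    control_values: pd.DataFrame,
    weights: ScmWeights,
    subgroup_series: pd.DataFrame,
    treatment_year: int,
) -> EqualityTest:
    """Stacked weighted TWFE regression testing subgroup effect equality.

    Parameters
    ----------
    control_values
        Long frame ``unit, year, value`` for the control districts (one
        outcome).  Controls enter with their synthetic-control weights;
        zero-weight controls are excluded (they carry no information and
        would make the weighted design singular).
    subgroup_series
        Frame indexed by year with columns ``s0`` and ``s1``: the treated
        unit's yearly subgroup means, entering unweighted.

    The regression is  value ~ unit FE + year FE + post*treated +
    post*treated*(s=1); the triple interaction estimates
    ATT(s=1) - ATT(s=0) with an HC3 heteroskedasticity-robust SE.
    """
    for col in ("s0", "s1"):
        if col not in subgroup_series.columns:
            raise MissingDataError(f"subgroup series missing column {col!r}")
    years = subgroup_series.index.to_numpy()
    if subgroup_series[["s0", "s1"]].isna().any().any():
        bad = subgroup_series.index[subgroup_series[["s0", "s1"]].isna().any(axis=1)]
        raise MissingDataError(f"subgroup series missing years {list(bad)}")

    w_map = {i: w for i, w in zip(weights.control_ids, weights.values) if w > 0}
    ctrl = control_values[control_values["unit"].isin(w_map)].copy()
    ctrl["weight"] = ctrl["unit"].map(w_map)
    ctrl = ctrl[ctrl["year"].isin(years)]
    ctrl["post_treated"] = 0.0
    ctrl["post_treated_s1"] = 0.0

    frames = [ctrl[["unit", "year", "value", "weight", "post_treated", "post_treated_s1"]]]
    for s, col in ((0, "s0"), (1, "s1")):
        block = pd.DataFrame(
            {
                "unit": f"__treated_s{s}__",
                "year": years,
                "value": subgroup_series[col].to_numpy(float),
                "weight": 1.0,
                "post_treated": (years >= treatment_year).astype(float),
                "post_treated_s1": ((years >= treatment_year) & (s == 1)).astype(float),
            }
        )
        frames.append(block)
    data = pd.concat(frames, ignore_index=True)

    unit_d = pd.get_dummies(data["unit"], prefix="u", drop_first=True, dtype=float)
    year_d = pd.get_dummies(data["year"], prefix="t", drop_first=True, dtype=float)
    X = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="const"),
            unit_d,
            year_d,
            data[["post_treated", "post_treated_s1"]],
        ],
        axis=1,
    )
    Xw = X.to_numpy() * np.sqrt(data["weight"].to_numpy())[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise RankError("collinear TWFE design (too few periods or missing cells)")

    model = sm.WLS(data["value"].to_numpy(float), X, weights=data["weight"].to_numpy())
    fitted = model.fit(cov_type="HC3")
    est = float(fitted.params["post_treated_s1"])
    se = float(fitted.bse["post_treated_s1"])
    p = float(fitted.pvalues["post_treated_s1"])
    return EqualityTest(estimate=est, se=se, pvalue=p)
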