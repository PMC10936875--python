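"""Demeaned (intercept-shift) synthetic control with joint multi-outcome weights.

The estimator first subtracts each unit's pretreatment mean of an outcome
from every observation of that unit (a unit fixed effect), then finds a
single simplex-constrained weight vector over control districts that makes
the weighted control aggregate track the treated unit's *demeaned*
pretreatment trajectories of all selected outcomes simultaneously.  Because
only trends are matched, a treated unit whose levels are extreme outliers
can still have good common support.

With weights w on the unit simplex the post/pre-differenced estimate

    ATT = (Ybar_1 - Xbar_1) - sum_i w_i (Ybar_i - Xbar_i)

is identically a weighted two-period difference-in-differences: Xbar/Ybar
are a unit's pre/post period means of the outcome.  Outcomes enter the
weight objective on a common scale, each divided by its pooled pretreatment
standard deviation across the analytic sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .errors import MissingDataError, SchemaError, SolverError

#: Weights smaller than this are reported as exactly zero (then renormalized).
WEIGHT_FLOOR = 1e-6
#: Ridge on w breaking ties among non-unique minimizers (collinear controls).
DEFAULT_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Panel helpers
# ---------------------------------------------------------------------------

def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in ("unit", "year", "outcome", "value") if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing column(s): {missing}")


def _wide(panel: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Year x unit table of one outcome's values."""
    sub = panel[panel["outcome"] == outcome]
    if sub.empty:
        raise MissingDataError(f"outcome {outcome!r} not present in panel")
    return sub.pivot_table(index="year", columns="unit", values="value", aggfunc="first")


def _pre_means(wide: pd.DataFrame, treatment_year: int) -> pd.Series:
    pre = wide.loc[wide.index < treatment_year]
    if pre.empty:
        raise MissingDataError("no pretreatment years in panel")
    return pre.mean(axis=0)


def demean(
    panel: pd.DataFrame,
    outcome: str,
    treatment_year: int,
    treated_id=None,
) -> pd.DataFrame:
    """Subtract each unit's pretreatment mean from all its observations.

    Units with no pretreatment observation of the outcome are dropped with a
    warning — unless the unit is the treated one, which is a hard error.
    Returns a long frame ``unit, year, resid, period``.
    """
    _check_panel(panel)
    wide = _wide(panel, outcome)
    means = _pre_means(wide, treatment_year)
    missing = means[means.isna()].index.tolist()
    if missing:
        if treated_id is not None and treated_id in missing:
            raise MissingDataError(
                f"treated unit {treated_id!r} has no pretreatment data for {outcome!r}"
            )
        warnings.warn(f"units {missing} have no pretreatment {outcome!r} data; dropped")
        wide = wide.drop(columns=missing)
        means = means.drop(missing)
    resid = wide - means
    out = resid.reset_index().melt(id_vars="year", var_name="unit", value_name="resid")
    out = out.dropna(subset=["resid"])
    out["period"] = np.where(out["year"] < treatment_year, "pre", "post")
    return out.sort_values(["unit", "year"], ignore_index=True)


def pooled_pre_sd(panel: pd.DataFrame, outcome: str, units, treatment_year: int) -> float:
    """Population SD of an outcome's raw pretreatment values across the sample."""
    sub = panel[
        (panel["outcome"] == outcome)
        & (panel["year"] < treatment_year)
        & (panel["unit"].isin(list(units)))
    ]
    if sub.empty:
        raise MissingDataError(f"no pretreatment {outcome!r} values for scaling")
    sd = float(np.std(sub["value"].to_numpy(), ddof=0))
    if sd <= 0:
        raise MissingDataError(f"degenerate (zero) pretreatment SD for {outcome!r}")
    return sd


# ---------------------------------------------------------------------------
# Simplex-constrained least squares
# ---------------------------------------------------------------------------

def _kkt_solve(G: np.ndarray, c: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Equality-constrained minimizer of w'Gw - 2c'w with sum(w[idx]) = 1."""
    k = len(idx)
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2 * G[np.ix_(idx, idx)]
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2 * c[idx], [1.0]])
    try:
        return np.linalg.solve(kkt, rhs)[:k]
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(kkt, rhs, rcond=None)[0][:k]


def solve_simplex_lsq(
    A: np.ndarray, b: np.ndarray, ridge: float = DEFAULT_RIDGE, tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """min_w ||A w - b||^2 + ridge ||w||^2  s.t.  w >= 0, sum w = 1.

    Active-set iteration on the KKT system, warm-started from a
    penalty-augmented NNLS solution; the bound multipliers are checked so
    the returned point satisfies the KKT conditions of the convex program.
    Deterministic for fixed inputs.  Falls back to SLSQP if the active-set
    loop stalls.  Returns (w, objective) with the ridge term excluded from
    the reported objective.
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    n = A.shape[1]
    G = A.T @ A + ridge * np.eye(n)
    c = A.T @ b

    def obj(w):
        return float(w @ G @ w - 2 * c @ w + b @ b)

    if n == 1:
        w = np.array([1.0])
        return w, obj(w) - ridge

    # warm start: sum-to-one as a stiff penalty row makes this plain NNLS
    lam = 10.0 * max(1.0, float(np.abs(A).max())) * max(A.shape[0], n)
    A2 = np.vstack([A, np.sqrt(ridge) * np.eye(n), lam * np.ones((1, n))])
    b2 = np.concatenate([b, np.zeros(n), [lam]])
    w0, _ = nnls(A2, b2)
    support = w0 > 1e-12
    if not support.any():
        support[:] = True

    solved = False
    for _ in range(4 * n):
        idx = np.where(support)[0]
        ws = _kkt_solve(G, c, idx)
        if (ws < -1e-10).any():
            support[idx[np.argmin(ws)]] = False
            continue
        w = np.zeros(n)
        w[idx] = np.clip(ws, 0.0, None)
        grad = 2 * (G @ w - c)
        mu = float(np.mean(grad[idx]))  # stationarity multiplier on the support
        eta = grad - mu  # bound multipliers; must be >= 0 off support
        violators = np.where(~support & (eta < -1e-9 * max(1.0, abs(mu))))[0]
        if violators.size == 0:
            solved = True
            break
        support[violators[np.argmin(eta[violators])]] = True

    if not solved:  # pragma: no cover - stalled active set
        res = minimize(
            obj,
            np.full(n, 1.0 / n),
            jac=lambda w: 2 * (G @ w - c),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"ftol": 1e-14, "maxiter": 1000},
        )
        if not res.success:
            raise SolverError(f"weight solver failed: {res.message}")
        w = np.clip(res.x, 0.0, None)
        w /= w.sum()

    w[w < WEIGHT_FLOOR] = 0.0
    total = w.sum()
    if total <= 0:
        raise SolverError("all weights fell below the reporting floor")
    w /= total
    return w, obj(w) - ridge * float(w @ w)


# ---------------------------------------------------------------------------
# Weight fitting on demeaned pretreatment trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScmWeights:
    """Simplex weights over the control districts."""

    control_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if abs(v.sum() - 1.0) > 1e-8:
            raise SolverError(f"weights sum to {v.sum():.10f}, not 1")
        if (v < -1e-12).any():
            raise SolverError("negative weight")
        object.__setattr__(self, "values", np.clip(v, 0.0, None))

    def as_dict(self) -> dict:
        return {str(i): float(w) for i, w in zip(self.control_ids, self.values)}

    def reindex(self, ids) -> np.ndarray:
        d = dict(zip(self.control_ids, self.values))
        return np.array([d[i] for i in ids])


def stack_design(
    panel: pd.DataFrame,
    treated_id,
    control_ids,
    outcomes,
    treatment_year: int,
    scales: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stacked (A, b) of scaled demeaned pretreatment rows across outcomes.

    Each outcome contributes one row per pretreatment year in its
    availability window, divided by that outcome's pooled pretreatment SD so
    achievement scores (SD units) and classification rates (proportions)
    are balanced on a common scale.
    """
    control_ids = list(control_ids)
    units = [treated_id] + control_ids
    rows_a, rows_b = [], []
    realized_scales = {}
    for outcome in outcomes:
        wide = _wide(panel, outcome)
        missing_units = [u for u in units if u not in wide.columns]
        if missing_units:
            raise MissingDataError(f"units {missing_units} missing outcome {outcome!r}")
        wide = wide[units]
        means = _pre_means(wide, treatment_year)
        if means.isna().any():
            raise MissingDataError(
                f"units {means[means.isna()].index.tolist()} lack pretreatment {outcome!r}"
            )
        resid = wide - means
        pre = resid.loc[resid.index < treatment_year].dropna(axis=0, how="any")
        scale = (
            scales[outcome]
            if scales is not None
            else pooled_pre_sd(panel, outcome, units, treatment_year)
        )
        realized_scales[outcome] = float(scale)
        rows_b.append(pre[treated_id].to_numpy() / scale)
        rows_a.append(pre[control_ids].to_numpy() / scale)
    A = np.vstack(rows_a)
    b = np.concatenate(rows_b)
    return A, b, realized_scales


def fit_weights(
    panel: pd.DataFrame,
    treated_id,
    control_ids,
    outcomes,
    treatment_year: int,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[ScmWeights, float, dict]:
    """Fit one weight vector balancing all selected outcomes jointly."""
    control_ids = list(control_ids)
    if len(control_ids) < 1:
        raise MissingDataError("need at least one control unit")
    A, b, scales = stack_design(panel, treated_id, control_ids, outcomes, treatment_year)
    w, objective = solve_simplex_lsq(A, b, ridge=ridge)
    return ScmWeights(tuple(control_ids), w), objective, scales


# ---------------------------------------------------------------------------
# Effects and fit diagnostics
# ---------------------------------------------------------------------------

def _means_and_gaps(panel, weights: ScmWeights, outcome, treatment_year, treated_id):
    wide = _wide(panel, outcome)
    ids = [i for i in weights.control_ids]
    missing = [u for u in [treated_id] + ids if u not in wide.columns]
    if missing:
        raise MissingDataError(f"units {missing} missing outcome {outcome!r}")
    w = weights.reindex(ids)
    pre = wide.loc[wide.index < treatment_year]
    post = wide.loc[wide.index >= treatment_year]
    if post[treated_id].dropna().empty:
        raise MissingDataError(f"treated unit has no posttreatment {outcome!r} data")
    x_bar = pre.mean(axis=0)
    y_bar = post.mean(axis=0)
    means = {
        "x_treated": float(x_bar[treated_id]),
        "y_treated": float(y_bar[treated_id]),
        "x_synthetic": float(x_bar[ids] @ w),
        "y_synthetic": float(y_bar[ids] @ w),
    }
    resid = wide - x_bar
    gaps = resid[treated_id] - resid[ids] @ w
    gaps = gaps.dropna()
    return means, gaps


def compute_att(
    panel: pd.DataFrame,
    weights: ScmWeights,
    outcome: str,
    treatment_year: int,
    treated_id,
) -> tuple[float, pd.Series, dict]:
    """ATT and the yearly treated-minus-synthetic gap series (demeaned scale).

    The post/pre-differenced form and the mean of post-year gaps agree to
    machine precision; both are pure functions of the panel and weights.
    """
    means, gaps = _means_and_gaps(panel, weights, outcome, treatment_year, treated_id)
    att = (means["y_treated"] - means["x_treated"]) - (
        means["y_synthetic"] - means["x_synthetic"]
    )
    return float(att), gaps.rename("gap"), means


def pre_rmse(
    panel: pd.DataFrame,
    weights: ScmWeights,
    outcome: str,
    treatment_year: int,
    treated_id,
) -> float:
    """Root mean squared pretreatment gap, in the outcome's native units."""
    _, gaps = _means_and_gaps(panel, weights, outcome, treatment_year, treated_id)
    g = gaps[gaps.index < treatment_year].to_numpy()
    return float(np.sqrt(np.mean(g**2)))


def overall_rmse(
    panel: pd.DataFrame,
    weights: ScmWeights,
    outcomes,
    treatment_year: int,
    treated_id,
    scales: dict | None = None,
) -> float:
    """Pretreatment RMSE pooled across outcomes on a standardized scale.

    Each outcome's gaps are divided by its pooled pretreatment SD within
    the analytic sample before pooling, so the statistic is invariant to
    rescaling any single outcome.
    """
    units = [treated_id] + list(weights.control_ids)
    sq = []
    for outcome in outcomes:
        _, gaps = _means_and_gaps(panel, weights, outcome, treatment_year, treated_id)
        g = gaps[gaps.index < treatment_year].to_numpy()
        scale = (
            scales[outcome]
            if scales is not None and outcome in scales
            else pooled_pre_sd(panel, outcome, units, treatment_year)
        )
        sq.append((g / scale) ** 2)
    return float(np.sqrt(np.mean(np.concatenate(sq))))


@dataclass
class ScmFit:
    """Bundle of weights, effects, gap series, and fit diagnostics."""

    treated_id: object
    weights: ScmWeights
    outcomes_fitted: tuple
    att: dict = field(default_factory=dict)
    gaps: dict = field(default_factory=dict)
    pre_rmse: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    overall_rmse: float = float("nan")
    objective: float = float("nan")

    @property
    def outcomes(self) -> tuple:
        return tuple(self.att.keys())

    def to_dict(self) -> dict:
        return {
            "treated_id": str(self.treated_id),
            "weights": self.weights.as_dict(),
            "outcomes_fitted": [str(o) for o in self.outcomes_fitted],
            "att": {k: float(v) for k, v in self.att.items()},
            "pre_rmse": {k: float(v) for k, v in self.pre_rmse.items()},
            "overall_rmse": float(self.overall_rmse),
            "objective": float(self.objective),
            "scales": {k: float(v) for k, v in self.scales.items()},
            "means": self.means,
            "gaps": {
                k: {int(y): float(g) for y, g in s.items()} for k, s in self.gaps.items()
            },
        }


def fit_scm(
    panel: pd.DataFrame,
    treated_id,
    pool,
    outcome_subset=None,
    treatment_year: int = 2015,
    ridge: float = DEFAULT_RIDGE,
) -> ScmFit:
    """Full estimator: demean, fit joint weights, compute effects per outcome.

    Weights are fitted only on ``outcome_subset`` (default: every outcome in
    the panel, canonical order); ATT, gap series, and pre-RMSE are reported
    for every outcome present in the panel.
    """
    _check_panel(panel)
    from .panel import OUTCOMES  # canonical reporting order

    present = list(panel["outcome"].unique())
    ordered = [o for o in OUTCOMES if o in present] + sorted(set(present) - set(OUTCOMES))
    if outcome_subset is None:
        outcome_subset = ordered
    outcome_subset = list(outcome_subset)
    unknown = [o for o in outcome_subset if o not in present]
    if unknown:
        raise MissingDataError(f"requested outcomes not in panel: {unknown}")

    weights, objective, scales = fit_weights(
        panel, treated_id, list(pool), outcome_subset, treatment_year, ridge=ridge
    )
    fit = ScmFit(
        treated_id=treated_id,
        weights=weights,
        outcomes_fitted=tuple(outcome_subset),
        objective=objective,
        scales=scales,
    )
    for outcome in ordered:
        att, gaps, means = compute_att(panel, weights, outcome, treatment_year, treated_id)
        fit.att[outcome] = att
        fit.gaps[outcome] = gaps
        fit.means[outcome] = means
        fit.pre_rmse[outcome] = pre_rmse(panel, weights, outcome, treatment_year, treated_id)
    fit.overall_rmse = overall_rmse(
        panel, weights, ordered, treatment_year, treated_id
    )
    return fit
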