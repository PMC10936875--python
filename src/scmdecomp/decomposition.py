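"""Subgroup treatment-effect decomposition against a common synthetic control.

Each dichotomous subgroup s in {0,1} of the treated unit gets its own ATT,

    ATT^s = (Ybar_1^s - Xbar_1^s) - (Ybar_syn - Xbar_syn),

sharing the *overall* fit's synthetic aggregate — so the decomposition
works even for variables (like home service-line material) observed only
inside the treated unit.  The overall ATT decomposes exactly as

    ATT = p0 * ATT^{s=0} + p1 * ATT^{s=1}
          + dp1 * (Xbar_1^{s=1} - Xbar_1^{s=0}),

where p0/p1 are the post-period average shares of each category, and dp1 is
the post-minus-pre change in the s=1 share.  Here p multiplies the ATT of
the category it describes, and the adjustment sign follows from expanding
Ybar_1 - Xbar_1 with period shares (a category whose share grew
contributes its pretreatment mean with positive sign).  The identity is
exact whenever the treated unit's overall series is the share-weighted
average of the subgroup series with shares constant within each period;
with drifting shares the adjustment term absorbs the compositional change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, MissingDataError
from .panel import SUBGROUP_CATEGORIES, derive_subgroup
from .scm import ScmFit

PROP_TOL = 1e-8


@dataclass
class SubgroupPanel:
    """Treated-unit yearly subgroup means and category shares for one outcome."""

    variable: str
    outcome: str
    means: pd.DataFrame  # index year, columns [0, 1] (category s)
    props: pd.DataFrame  # index year, columns [0, 1], rows sum to 1
    treatment_year: int
    category_names: tuple = ("s0", "s1")

    def __post_init__(self):
        self.means = self.means.sort_index()
        self.props = self.props.sort_index()
        if list(self.means.columns) != [0, 1] or list(self.props.columns) != [0, 1]:
            raise ConsistencyError("subgroup frames need exactly the two columns [0, 1]")
        if not self.means.index.equals(self.props.index):
            raise ConsistencyError("subgroup means and proportions cover different years")
        p = self.props.to_numpy(float)
        if np.isnan(p).any() or (p < -PROP_TOL).any() or (p > 1 + PROP_TOL).any():
            raise ConsistencyError("subgroup proportions must lie in [0, 1]")
        if np.abs(p.sum(axis=1) - 1.0).max() > PROP_TOL:
            raise ConsistencyError("subgroup proportions do not sum to 1 within tolerance")

    @property
    def years(self) -> np.ndarray:
        return self.means.index.to_numpy()

    def overall_series(self) -> pd.Series:
        """Share-weighted yearly mean; equals the treated unit's overall series."""
        return (self.means * self.props).sum(axis=1)

    def period_stats(self) -> dict:
        pre = self.years < self.treatment_year
        post = ~pre
        if not pre.any() or not post.any():
            raise MissingDataError("subgroup panel needs both pre and post years")
        return {
            "x_s0": float(self.means.loc[pre, 0].mean()),
            "x_s1": float(self.means.loc[pre, 1].mean()),
            "y_s0": float(self.means.loc[post, 0].mean()),
            "y_s1": float(self.means.loc[post, 1].mean()),
            "p_pre_s1": float(self.props.loc[pre, 1].mean()),
            "p_post_s0": float(self.props.loc[post, 0].mean()),
            "p_post_s1": float(self.props.loc[post, 1].mean()),
        }

    def relabeled(self) -> "SubgroupPanel":
        """Swap which category is s=0; the decomposition must be invariant."""
        swap = {0: 1, 1: 0}
        return SubgroupPanel(
            variable=self.variable,
            outcome=self.outcome,
            means=self.means.rename(columns=swap)[[0, 1]],
            props=self.props.rename(columns=swap)[[0, 1]],
            treatment_year=self.treatment_year,
            category_names=(self.category_names[1], self.category_names[0]),
        )


def subgroup_panel_from_students(
    records: pd.DataFrame,
    variable: str,
    outcome: str,
    treated_id,
    treatment_year: int,
    windows: dict | None = None,
    ses_labels: pd.DataFrame | None = None,
) -> SubgroupPanel:
    """Build the treated unit's subgroup panel from student-level records.

    Only rows with a defined subgroup label and a non-missing outcome value
    contribute (service-line labels, for instance, exist only for
    address-matched students).
    """
    from .panel import DEFAULT_WINDOWS, OUTCOME_COLUMNS

    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    col = OUTCOME_COLUMNS[outcome]
    labels = derive_subgroup(records, variable, treated_id=treated_id, ses_labels=ses_labels)
    sub = records.assign(s=labels["s"].astype("Float64"))
    sub = sub[
        (sub["district_of_residence"] == treated_id)
        & sub["s"].notna()
        & sub[col].notna()
        & (sub["year"] >= windows.get(outcome, sub["year"].min()))
    ]
    if sub.empty:
        raise MissingDataError(f"no labeled treated-unit rows for {variable}/{outcome}")
    means = sub.pivot_table(index="year", columns="s", values=col, aggfunc="mean")
    counts = sub.pivot_table(index="year", columns="s", values=col, aggfunc="count")
    means.columns = [int(c) for c in means.columns]
    counts.columns = [int(c) for c in counts.columns]
    for c in (0, 1):
        if c not in means.columns:
            raise MissingDataError(f"subgroup category {c} absent for {variable}/{outcome}")
    props = counts[[0, 1]].div(counts[[0, 1]].sum(axis=1), axis=0)
    return SubgroupPanel(
        variable=variable,
        outcome=outcome,
        means=means[[0, 1]],
        props=props,
        treatment_year=treatment_year,
        category_names=SUBGROUP_CATEGORIES[variable],
    )


def subgroup_att(
    sp: SubgroupPanel, syn_pre: float, syn_post: float
) -> tuple[float, float]:
    """Per-category ATT against a shared synthetic aggregate's period means."""
    st = sp.period_stats()
    syn = syn_post - syn_pre
    return (st["y_s0"] - st["x_s0"] - syn, st["y_s1"] - st["x_s1"] - syn)


@dataclass
class SubgroupDecomposition:
    """Both subgroup ATTs, the compositional adjustment, and the reconstruction."""

    variable: str
    outcome: str
    category_names: tuple
    att_s0: float
    att_s1: float
    p_s0: float  # post-period average share of category 0
    p_s1: float
    delta_p1: float  # post-minus-pre change in the s=1 share
    x_pre_s0: float
    x_pre_s1: float
    adjustment: float
    reconstructed_att: float
    overall_att: float | None = None
    se_s0: float | None = None
    se_s1: float | None = None
    equality_p: float | None = None

    def to_rows(self) -> list[dict]:
        common = {
            "variable": self.variable,
            "outcome": self.outcome,
            "adjustment": self.adjustment,
            "reconstructed_att": self.reconstructed_att,
            "overall_att": self.overall_att,
            "equality_p": self.equality_p,
        }
        return [
            {
                "category": self.category_names[0],
                "p": self.p_s0,
                "att": self.att_s0,
                "se": self.se_s0,
                **common,
            },
            {
                "category": self.category_names[1],
                "p": self.p_s1,
                "att": self.att_s1,
                "se": self.se_s1,
                **common,
            },
        ]


def decompose(
    sp: SubgroupPanel,
    syn_pre: float,
    syn_post: float,
    overall_att: float | None = None,
) -> SubgroupDecomposition:
    """Decompose the overall ATT into subgroup ATTs plus a composition term."""
    st = sp.period_stats()
    att0, att1 = subgroup_att(sp, syn_pre, syn_post)
    delta_p1 = st["p_post_s1"] - st["p_pre_s1"]
    adjustment = delta_p1 * (st["x_s1"] - st["x_s0"])
    reconstructed = st["p_post_s0"] * att0 + st["p_post_s1"] * att1 + adjustment
    return SubgroupDecomposition(
        variable=sp.variable,
        outcome=sp.outcome,
        category_names=sp.category_names,
        att_s0=att0,
        att_s1=att1,
        p_s0=st["p_post_s0"],
        p_s1=st["p_post_s1"],
        delta_p1=delta_p1,
        x_pre_s0=st["x_s0"],
        x_pre_s1=st["x_s1"],
        adjustment=adjustment,
        reconstructed_att=reconstructed,
        overall_att=overall_att,
    )


def decompose_fit(fit: ScmFit, sp: SubgroupPanel) -> SubgroupDecomposition:
    """Decompose using an overall :class:`ScmFit`'s synthetic means for the outcome."""
    if sp.outcome not in fit.means:
        raise MissingDataError(f"fit has no outcome {sp.outcome!r}")
    m = fit.means[sp.outcome]
    return decompose(
        sp, m["x_synthetic"], m["y_synthetic"], overall_att=float(fit.att[sp.outcome])
    )
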