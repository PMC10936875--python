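"""District-year panel construction from student-level records.

The analysis operates on a long-format district x year x outcome table built
by collapsing annual student records.  A "year" label always denotes the
spring of a school year, so with a treatment year of 2015 the school year
2014-15 is the first post-treatment observation.  Outcomes have distinct
availability windows: standardized achievement starts in 2007 (grades 3-8
only), special-needs classification in 2006, and daily attendance in 2009.

This module also derives the dichotomous student subgroups used by the
treatment-effect decomposition: gender, grade band (<=5 vs >=6), a
PCA-based socioeconomic index, district mobility, and home water
service-line material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateCellError, MissingDataError, SchemaError

#: Canonical outcome names, in reporting order.
OUTCOMES = ("math", "reading", "special_needs", "attendance")

#: Student-record column holding each outcome.
OUTCOME_COLUMNS = {
    "math": "math_score",
    "reading": "reading_score",
    "special_needs": "special_needs",
    "attendance": "attendance_rate",
}

#: First calendar year each outcome is observed.
DEFAULT_WINDOWS = {"math": 2007, "reading": 2007, "special_needs": 2006, "attendance": 2009}

#: Grades in which state achievement tests are administered.
ACHIEVEMENT_GRADES = (3, 8)

SUBGROUP_VARIABLES = ("gender", "grade_band", "ses", "mobility", "service_line")

#: Category names per subgroup variable, indexed by s in {0, 1}.
SUBGROUP_CATEGORIES = {
    "gender": ("male", "female"),
    "grade_band": ("grade<=5", "grade>=6"),
    "ses": ("below_median", "above_median"),
    "mobility": ("immobile", "mobile"),
    "service_line": ("copper", "lead"),
}

STUDENT_COLUMNS = [
    "student_id",
    "year",
    "district_of_residence",
    "district_attended",
    "grade",
    "gender",
    "math_score",
    "reading_score",
    "special_needs",
    "attendance_rate",
    "econ_disadvantaged",
    "snap",
    "tanf",
    "graduated_flag",
    "address_key",
]


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def reference_from_scores(
    scores: pd.DataFrame,
    cell_cols=("grade", "subject", "year"),
    value_col: str = "score",
) -> pd.DataFrame:
    """Per-cell mean and population SD computed from a score table.

    Used when the statewide reference distribution is the sample itself.
    The SD divides by n (population convention): the z-scores are taken
    against a full-population distribution, not an estimate of it.
    """
    _require_columns(scores, list(cell_cols) + [value_col], "score table")
    grouped = scores.groupby(list(cell_cols))[value_col]
    ref = grouped.agg(mean="mean", sd=lambda x: float(np.std(x.dropna(), ddof=0)))
    return ref.reset_index()


def standardize_achievement(
    scores: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    cell_cols=("grade", "subject", "year"),
    value_col: str = "score",
) -> pd.Series:
    """z-score achievement within grade-subject-year cells.

    Each cell is standardized independently against its reference mean and
    SD; missing scores stay missing.  A cell whose reference SD is zero or
    missing raises :class:`DegenerateCellError` naming the cell.
    """
    cell_cols = list(cell_cols)
    _require_columns(scores, cell_cols + [value_col], "score table")
    if reference is None:
        reference = reference_from_scores(scores, cell_cols, value_col)
    _require_columns(reference, cell_cols + ["mean", "sd"], "reference table")

    merged = scores[cell_cols + [value_col]].merge(
        reference[cell_cols + ["mean", "sd"]], on=cell_cols, how="left", validate="m:1"
    )
    observed = merged[value_col].notna()
    bad = observed & (merged["sd"].isna() | (merged["sd"] <= 0))
    if bad.any():
        cell = tuple(merged.loc[bad.idxmax(), cell_cols])
        raise DegenerateCellError(
            f"cell {dict(zip(cell_cols, cell))} has zero or missing reference SD"
        )
    z = (merged[value_col] - merged["mean"]) / merged["sd"]
    z.index = scores.index
    return z.rename("z")


# ---------------------------------------------------------------------------
# Collapsing to the district-year panel
# ---------------------------------------------------------------------------

def collapse_to_panel(
    records: pd.DataFrame,
    treatment_year: int = 2015,
    assignment: str = "contemporaneous",
    base_year: int | None = None,
    windows: dict | None = None,
) -> pd.DataFrame:
    """Collapse student records to a long district-year-outcome panel.

    Parameters
    ----------
    records
        One row per student-year with the :data:`STUDENT_COLUMNS` schema.
    assignment
        ``"contemporaneous"`` groups students by their district of residence
        in each year.  ``"invariant"`` freezes each student's district at
        ``base_year`` (students unobserved in the base year are dropped), the
        standard guard against post-treatment selective mobility.
    windows
        Mapping outcome -> first observed year; defaults to
        :data:`DEFAULT_WINDOWS`.

    Returns
    -------
    DataFrame with columns ``unit, year, outcome, value, n, period``.
    Empty district-year-outcome cells are omitted, never zero-filled.
    """
    if records is None or len(records) == 0:
        raise MissingDataError("cannot collapse an empty record set")
    _require_columns(records, ["student_id", "year", "district_of_residence"], "student records")
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)

    records = records.copy()
    if assignment == "contemporaneous":
        records["unit"] = records["district_of_residence"]
    elif assignment == "invariant":
        if base_year is None:
            raise ConfigError("invariant assignment requires a base_year")
        base = records.loc[records["year"] == base_year, ["student_id", "district_of_residence"]]
        if base.empty:
            raise ConfigError(f"base_year {base_year} not present in the records")
        mapping = base.drop_duplicates("student_id").set_index("student_id")[
            "district_of_residence"
        ]
        records["unit"] = records["student_id"].map(mapping)
        records = records[records["unit"].notna()]
    else:
        raise ConfigError(f"unknown assignment mode {assignment!r}")

    pieces = []
    for outcome, col in OUTCOME_COLUMNS.items():
        if col not in records.columns:
            continue
        sub = records[records["year"] >= windows.get(outcome, records["year"].min())]
        sub = sub[sub[col].notna()]
        if sub.empty:
            continue
        cell = (
            sub.groupby(["unit", "year"])[col]
            .agg(value="mean", n="count")
            .reset_index()
        )
        cell["outcome"] = outcome
        pieces.append(cell)
    if not pieces:
        raise MissingDataError("no outcome columns found in the student records")
    panel = pd.concat(pieces, ignore_index=True)
    panel["period"] = np.where(panel["year"] < treatment_year, "pre", "post")
    panel = panel[["unit", "year", "outcome", "value", "n", "period"]]
    return panel.sort_values(["outcome", "unit", "year"], ignore_index=True)


# ---------------------------------------------------------------------------
# Socioeconomic index
# ---------------------------------------------------------------------------

@dataclass
class SesIndex:
    """First-principal-component socioeconomic index over three poverty markers."""

    labels: pd.DataFrame  # student_id, score, s, category
    explained_variance_ratio: float
    correlations: dict = field(default_factory=dict)


def ses_index(records: pd.DataFrame) -> SesIndex:
    """Dichotomize students by the first PC of their poverty-marker averages.

    For each student the yearly indicators of economic disadvantage, SNAP
    receipt, and TANF receipt are averaged over the years the student is
    observed.  The first principal component of the correlation matrix of
    the three averages, oriented so that higher scores mean more
    disadvantage, is split at its median: scores at or above the median are
    labelled ``below_median`` (socioeconomic status below the median, s=0).
    """
    cols = ["econ_disadvantaged", "snap", "tanf"]
    _require_columns(records, ["student_id"] + cols, "student records")
    means = records.groupby("student_id")[cols].mean()
    means = means.dropna(how="any")
    if len(means) < 2:
        raise MissingDataError("PCA undefined with fewer than 2 students")

    sds = means.std(ddof=0)
    keep = [c for c in cols if sds[c] > 0]
    for c in cols:
        if c not in keep:
            warnings.warn(f"ses_index: {c} has zero variance and was dropped")
    if len(keep) < 2:
        raise MissingDataError("fewer than two poverty markers with variance; PCA undefined")

    z = (means[keep] - means[keep].mean()) / sds[keep]
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    pc1 = eigvec[:, -1]
    if pc1[keep.index("econ_disadvantaged")] < 0 if "econ_disadvantaged" in keep else pc1.sum() < 0:
        pc1 = -pc1
    score = z.to_numpy() @ pc1
    evr = float(eigval[-1] / eigval.sum())

    median = float(np.median(score))
    s = (score < median).astype(int)  # high score = disadvantaged = below-median SES = s=0
    labels = pd.DataFrame(
        {
            "student_id": means.index,
            "score": score,
            "s": s,
            "category": np.where(s == 0, "below_median", "above_median"),
        }
    ).reset_index(drop=True)
    correlations = {
        c: float(np.corrcoef(score, means[c])[0, 1]) if c in keep else float("nan")
        for c in cols
    }
    return SesIndex(labels=labels, explained_variance_ratio=evr, correlations=correlations)


# ---------------------------------------------------------------------------
# Subgroup derivation
# ---------------------------------------------------------------------------

def classify_service_line(material) -> "pd.Series | str":
    """Map free-text service-line inspection labels to {lead, copper, unlabeled}.

    Lead, galvanized steel, and nonstandard materials all posed a leaching
    risk and are pooled as "lead"; copper maps to "copper"; missing or
    unrecognized labels become "unlabeled" (with a warning for the latter).
    """
    scalar = np.isscalar(material) or material is None or material is pd.NA
    values = pd.Series([material]) if scalar else pd.Series(material)
    norm = values.astype("string").str.strip().str.lower()
    out = pd.Series("unlabeled", index=values.index, dtype=object)
    lead_like = norm.str.contains("lead|galvanized|nonstandard|non-standard", regex=True)
    out[lead_like.fillna(False)] = "lead"
    out[norm.fillna("").eq("copper")] = "copper"
    recognized = lead_like.fillna(False) | norm.fillna("").eq("copper") | norm.isna() | norm.eq("")
    if (~recognized).any():
        bad = sorted(norm[~recognized].unique())
        warnings.warn(f"unrecognized service-line material label(s) {bad} mapped to 'unlabeled'")
    if scalar:
        return out.iloc[0]
    out.index = values.index
    return out


def derive_subgroup(
    records: pd.DataFrame,
    variable: str,
    treated_id=None,
    ses_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binary subgroup label per student-year row.

    Returns a DataFrame aligned with ``records`` holding ``s`` (0/1, nullable
    Int64) and ``category``.  Grade band is the only time-varying label; all
    others are constant within student.  Mobility needs ``treated_id``: a
    student is mobile if they ever attend a district other than the treated
    one, or if their record ends before the final observed year without a
    graduation flag.  Service-line labels exist only for address-matched
    students; everyone else is left unlabeled (NA).
    """
    if variable not in SUBGROUP_VARIABLES:
        raise ConfigError(f"unknown subgroup variable {variable!r}")
    cat = SUBGROUP_CATEGORIES[variable]

    if variable == "gender":
        norm = records["gender"].astype("string").str.lower().str.strip()
        s = norm.map({"male": 0, "m": 0, "female": 1, "f": 1})
    elif variable == "grade_band":
        s = (records["grade"] >= 6).astype(int)
    elif variable == "ses":
        if ses_labels is None:
            ses_labels = ses_index(records).labels
        mapping = ses_labels.set_index("student_id")["s"]
        s = records["student_id"].map(mapping)
    elif variable == "mobility":
        if treated_id is None:
            raise ConfigError("mobility labels require treated_id")
        _require_columns(records, ["district_attended", "graduated_flag"], "student records")
        last_panel_year = int(records["year"].max())
        per = records.groupby("student_id").agg(
            ever_other=("district_attended", lambda d: bool((d != treated_id).any())),
            last_year=("year", "max"),
            graduated=("graduated_flag", lambda g: bool(pd.Series(g).fillna(0).astype(int).any())),
        )
        mobile = per["ever_other"] | ((per["last_year"] < last_panel_year) & ~per["graduated"])
        s = records["student_id"].map(mobile.astype(int))
    else:  # service_line
        _require_columns(records, ["service_line_material"], "student records")
        per = records.groupby("student_id")["service_line_material"].first()
        material = classify_service_line(per)
        sl = material.map({"copper": 0, "lead": 1})
        s = records["student_id"].map(pd.Series(sl.to_numpy(), index=per.index))

    s = pd.array(s, dtype="Int64")
    category = pd.Series(pd.NA, index=records.index, dtype=object)
    mask0 = (pd.Series(s) == 0).fillna(False).to_numpy(bool)
    mask1 = (pd.Series(s) == 1).fillna(False).to_numpy(bool)
    category.iloc[mask0] = cat[0]
    category.iloc[mask1] = cat[1]
    return pd.DataFrame({"s": s, "category": category}, index=records.index)
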