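"""Synthetic district panels and student records with known ground truth.

The generator emulates the statistical structure the estimator assumes: one
treated district plus a donor pool of candidate controls observed over a
14-year window, four outcomes with distinct availability windows, a linear
factor model driving common trends, and a student layer carrying the
dichotomous subgroups (gender, grade band, socioeconomic status, mobility,
service-line material) with configurable shares, baseline level gaps,
treatment-effect offsets, and compositional drift.

The interactive factor model for the untreated outcome surface is

    value(i, t, o) = a_io + lam_to + L_io . f_t + eps_ito,

with the treated unit's loadings drawn as a convex combination of control
loadings so a zero-bias synthetic match exists (switchable off for stress
tests).  Treatment adds tau_o(t) to the treated unit from the treatment
year onward.  At the student level effects enter additively and constant
within subgroup, so every estimand is available in closed form and is
recorded in :class:`SyntheticTruth` for recovery testing.

All randomness flows from one integer seed through ``numpy`` seed-sequence
spawning, so the panel, covariate, student, and linkage layers are each
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import DEFAULT_WINDOWS

TREATED_ID = "T1"


@dataclass(frozen=True)
class OutcomeSpec:
    """Generating parameters for one outcome.

    ``att`` is the treatment effect in outcome units (scalar, applied to
    every post year, or a year -> effect mapping).  ``student_sd`` and
    ``ability_loading`` control the student-level noise decomposition;
    ``grades`` restricts observation to a grade range (achievement tests).
    """

    first_year: int
    level_mean: float
    level_sd: float
    loading_sd: float
    shock_sd: float
    noise_sd: float
    att: float | dict = 0.0
    student_sd: float = 0.0
    ability_loading: float = 0.0
    grades: tuple | None = None
    kind: str = "continuous"  # continuous | binary | rate


#: Study-like defaults: achievement in statewide SD units with a -0.15 SD
#: math effect, special-needs and attendance as proportions with small
#: effects, and noise levels giving pretreatment RMSEs of the magnitude a
#: well-fitting district panel exhibits.
DEFAULT_OUTCOMES = {
    "math": OutcomeSpec(2007, -0.30, 0.15, 0.06, 0.015, 0.02, -0.15, 0.85, 0.45, (3, 8)),
    "reading": OutcomeSpec(2007, -0.30, 0.15, 0.06, 0.015, 0.02, -0.005, 0.85, 0.45, (3, 8)),
    "special_needs": OutcomeSpec(
        2006, 0.15, 0.02, 0.008, 0.002, 0.003, 0.012, 0.0, -0.03, None, "binary"
    ),
    "attendance": OutcomeSpec(
        2009, 0.94, 0.012, 0.005, 0.002, 0.003, -0.002, 0.03, 0.005, None, "rate"
    ),
}


@dataclass(frozen=True)
class SubgroupSpec:
    """Share, baseline level gaps, and treatment-effect gaps for one subgroup.

    ``level_diff``/``effect_diff`` map outcome -> (category 1 minus
    category 0); ``post_drift`` adds category-0 attrition in the treated
    unit post-treatment, drifting the s=1 share upward.
    """

    share_s1: float = 0.5
    level_diff: dict = field(default_factory=dict)
    effect_diff: dict = field(default_factory=dict)
    post_drift: float = 0.0


#: Effect heterogeneity of the magnitude reported for the Flint analysis:
#: special-needs effects concentrated among boys, math effects larger for
#: younger, low-SES, and lead-service-line students.
DEFAULT_SUBGROUPS = {
    "gender": SubgroupSpec(
        0.49,
        {"math": 0.03, "reading": 0.08, "special_needs": -0.092},
        {"math": 0.014, "special_needs": -0.017},
        0.002,
    ),
    "grade_band": SubgroupSpec(0.5, {}, {"math": 0.10}, 0.0),
    "ses": SubgroupSpec(0.5, {"math": 0.15, "reading": 0.15}, {"math": 0.061}, 0.0),
    "service_line": SubgroupSpec(0.4, {}, {"math": -0.03}, 0.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; every stochastic call requires a seed."""

    n_controls: int = 54
    years: tuple = (2006, 2019)
    treatment_year: int = 2015
    n_factors: int = 2
    outcomes: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    subgroups: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    treated_in_hull: bool = True
    n_background_districts: int = 350
    students_per_district: int = 120
    mobility_rate: float = 0.02
    attrition_rate: float = 0.01
    attend_other_rate: float = 0.03
    selective_mobility: float = 0.0
    lead_share: float = 0.4
    match_rate: float = 0.6

    def __post_init__(self):
        if self.n_controls < 1:
            raise ConfigError("need at least one control district")
        if self.years[0] >= self.years[1]:
            raise ConfigError("years must be an increasing (first, last) pair")
        if not (self.years[0] < self.treatment_year <= self.years[1]):
            raise ConfigError("treatment_year must fall inside the year range")
        for name, spec in self.outcomes.items():
            if not (self.years[0] <= spec.first_year <= self.years[1]):
                raise ConfigError(
                    f"availability window of {name!r} starts outside the year range"
                )
        for v in (self.lead_share, self.match_rate, self.mobility_rate, self.attrition_rate):
            if not (0 <= v <= 1):
                raise ConfigError("rates and shares must lie in [0, 1]")
        for name, sg in self.subgroups.items():
            if not (0 <= sg.share_s1 <= 1):
                raise ConfigError(f"subgroup {name!r} share outside [0, 1]")
        if self.students_per_district < 2:
            raise ConfigError("students_per_district must be at least 2")

    @property
    def treated_id(self) -> str:
        return TREATED_ID

    @property
    def control_ids(self) -> list:
        width = max(2, len(str(self.n_controls)))
        return [f"C{i:0{width}d}" for i in range(1, self.n_controls + 1)]

    @property
    def unit_ids(self) -> list:
        return [self.treated_id] + self.control_ids

    @property
    def year_range(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def att_by_year(self, outcome: str) -> dict:
        spec = self.outcomes[outcome]
        post = [int(y) for y in self.year_range if y >= self.treatment_year]
        if isinstance(spec.att, dict):
            return {int(y): float(spec.att.get(y, 0.0)) for y in post}
        return {y: float(spec.att) for y in post}


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to recompute every expected estimand."""

    treated_id: str
    att: dict  # outcome -> {year: tau}
    subgroup_att: dict  # variable -> outcome -> (att_s0, att_s1)
    hull_weights: dict | None
    loadings: dict  # outcome -> (n_units, k) array
    factors: np.ndarray  # (n_years, k)
    shocks: dict  # outcome -> (n_years,) array
    base_values: pd.DataFrame  # untreated outcome surface, long format

    def expected_att(self, outcome: str) -> float:
        taus = self.att[outcome]
        return float(np.mean(list(taus.values()))) if taus else 0.0


def _rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(4)
    return {
        name: np.random.default_rng(ss)
        for name, ss in zip(("panel", "covariates", "students", "linkage"), children)
    }


# ---------------------------------------------------------------------------
# District-year panel
# ---------------------------------------------------------------------------

def generate_panel(
    config: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a district-year-outcome panel, covariate table, and ground truth.

    Identical (config, seed) pairs produce byte-identical output.
    """
    rng = _rngs(seed)["panel"]
    years = config.year_range
    units = config.unit_ids
    n_units, n_years, k = len(units), len(years), config.n_factors
    outcomes = list(config.outcomes)

    factors = rng.standard_normal((n_years, k))
    hull = None
    loadings, shocks = {}, {}
    if config.treated_in_hull:
        omega = rng.dirichlet(np.ones(config.n_controls))
        hull = dict(zip(config.control_ids, omega))

    rows = []
    base_rows = []
    truth_att = {}
    for o in outcomes:
        spec = config.outcomes[o]
        a = rng.normal(spec.level_mean, spec.level_sd, n_units)
        L = rng.normal(0.0, spec.loading_sd, (n_units, k))
        if hull is not None:
            L[0] = omega @ L[1:]
        lam = rng.normal(0.0, spec.shock_sd, n_years)
        eps = rng.normal(0.0, spec.noise_sd, (n_units, n_years))
        base = a[:, None] + lam[None, :] + L @ factors.T + eps
        loadings[o] = L
        shocks[o] = lam

        taus = config.att_by_year(o)
        truth_att[o] = taus
        value = base.copy()
        for j, y in enumerate(years):
            if int(y) in taus:
                value[0, j] += taus[int(y)]

        keep = years >= spec.first_year
        for i, u in enumerate(units):
            for j in np.where(keep)[0]:
                rows.append((u, int(years[j]), o, float(value[i, j])))
                base_rows.append((u, int(years[j]), o, float(base[i, j])))

    panel = pd.DataFrame(rows, columns=["unit", "year", "outcome", "value"])
    panel["n"] = config.students_per_district
    panel["period"] = np.where(panel["year"] < config.treatment_year, "pre", "post")
    panel = panel.sort_values(["outcome", "unit", "year"], ignore_index=True)
    base_values = pd.DataFrame(base_rows, columns=["unit", "year", "outcome", "value"])

    subgroup_att = {}
    for var, sg in config.subgroups.items():
        per_outcome = {}
        for o in outcomes:
            tau = float(np.mean(list(truth_att[o].values()))) if truth_att[o] else 0.0
            diff = float(sg.effect_diff.get(o, 0.0))
            per_outcome[o] = (tau - sg.share_s1 * diff, tau + (1 - sg.share_s1) * diff)
        subgroup_att[var] = per_outcome

    truth = SyntheticTruth(
        treated_id=config.treated_id,
        att=truth_att,
        subgroup_att=subgroup_att,
        hull_weights=hull,
        loadings=loadings,
        factors=factors,
        shocks=shocks,
        base_values=base_values,
    )
    covariates = _generate_covariates(config, seed)
    return panel, covariates, truth


def _generate_covariates(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """District covariate table for the pool rules, reference-year values.

    Panel control districts are drawn in the extreme demographic region the
    donor-pool rules target (high fraction Black and/or high fraction
    economically disadvantaged); background districts without panel data
    fill in the rest of the state's distribution, including small districts
    that the enrollment filter removes.
    """
    rng = _rngs(seed)["covariates"]
    ref_year = config.treatment_year - 1
    rows = [
        {
            "district_id": config.treated_id,
            "enrollment": 16210,
            "fraction_black": 0.76,
            "fraction_econ_disadvantaged": 0.89,
            "year": ref_year,
        }
    ]
    kinds = rng.choice(3, size=config.n_controls, p=[0.4, 0.4, 0.2])
    for cid, kind in zip(config.control_ids, kinds):
        if kind == 0:  # high fraction Black
            fb, fe = rng.uniform(0.5, 0.95), rng.uniform(0.5, 0.85)
        elif kind == 1:  # high fraction econ. disadvantaged
            fb, fe = rng.uniform(0.05, 0.4), rng.uniform(0.8, 0.95)
        else:  # high on both
            fb, fe = rng.uniform(0.55, 0.95), rng.uniform(0.8, 0.95)
        rows.append(
            {
                "district_id": cid,
                "enrollment": int(np.clip(rng.lognormal(np.log(4000), 0.7), 1200, None)),
                "fraction_black": float(fb),
                "fraction_econ_disadvantaged": float(fe),
                "year": ref_year,
            }
        )
    for i in range(config.n_background_districts):
        rows.append(
            {
                "district_id": f"B{i + 1:03d}",
                "enrollment": int(rng.lognormal(np.log(1800), 1.0)),
                "fraction_black": float(rng.beta(0.6, 4.0)),
                "fraction_econ_disadvantaged": float(rng.uniform(0.2, 0.75)),
                "year": ref_year,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Student layer
# ---------------------------------------------------------------------------

def generate_students(
    config: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Student-year records whose district-year means reproduce the panel.

    Students progress one grade per year from kindergarten entry, may move
    between districts, attend a non-resident district, or leave the state
    system.  Treatment enters through residence: a student living in the
    treated district in a post year receives that year's effect, and a
    student exposed at the base year (the last pre-treatment year) keeps
    the effect after moving — so both contemporaneous and invariant
    district assignment target the configured ATT.  When
    ``selective_mobility`` > 0, higher-ability exposed students are more
    likely to leave the treated district post-treatment, inducing the
    compositional bias the invariant assignment is designed to remove.
    """
    _, _, truth = generate_panel(config, seed)
    rng = _rngs(seed)["students"]
    rng_link = _rngs(seed)["linkage"]
    years = config.year_range
    y0, y1 = int(years[0]), int(years[-1])
    base_year = config.treatment_year - 1
    units = config.unit_ids
    unit_index = {u: i for i, u in enumerate(units)}
    outcomes = list(config.outcomes)

    # lookup array of untreated panel values: (unit, year, outcome)
    base = np.full((len(units), len(years), len(outcomes)), np.nan)
    bv = truth.base_values
    oi = {o: j for j, o in enumerate(outcomes)}
    base[
        bv["unit"].map(unit_index).to_numpy(),
        bv["year"].to_numpy() - y0,
        bv["outcome"].map(oi).to_numpy(),
    ] = bv["value"].to_numpy()

    # --- student roster: cohorts entering kindergarten each year -------------
    per_cohort = max(1, round(config.students_per_district / 13))
    cohort_entries = np.arange(y0 - 12, y1 + 1)
    district0, entry = [], []
    for d in range(len(units)):
        for e in cohort_entries:
            district0.extend([d] * per_cohort)
            entry.extend([int(e)] * per_cohort)
    district0 = np.array(district0)
    entry = np.array(entry)
    n = len(entry)

    ability = rng.standard_normal(n)
    ses_latent = 0.4 * ability + np.sqrt(1 - 0.4**2) * rng.standard_normal(n)  # noqa: E226
    gender_s = (rng.random(n) < config.subgroups.get("gender", SubgroupSpec()).share_s1).astype(int)
    ses_s1 = (ses_latent < np.median(ses_latent)).astype(int)  # above-median SES

    # --- residence trajectories ----------------------------------------------
    n_years = len(years)
    residence = np.full((n, n_years), -1, dtype=int)
    current = district0.copy()
    alive = np.ones(n, dtype=bool)
    graduated = np.zeros(n, dtype=bool)
    drift_vars = [
        (v, sg)
        for v, sg in config.subgroups.items()
        if sg.post_drift > 0 and v in ("gender", "ses")
    ]
    s_lookup = {"gender": gender_s, "ses": ses_s1}
    for j, y in enumerate(years):
        grade = y - entry
        active = alive & (grade >= 0) & (grade <= 12)
        residence[active, j] = current[active]
        graduated |= active & (grade == 12)
        # transitions into next year
        post = y >= config.treatment_year
        leave_p = np.full(n, config.attrition_rate)
        if post:
            in_treated = active & (current == 0)
            for var, sg in drift_vars:
                leave_p = np.where(
                    in_treated & (s_lookup[var] == 0), leave_p + sg.post_drift, leave_p
                )
        leaves = active & (rng.random(n) < leave_p)
        alive &= ~leaves
        move_p = np.full(n, config.mobility_rate)
        if post and config.selective_mobility > 0:
            move_p = np.where(
                active & (current == 0) & (ability > 0),
                move_p + config.selective_mobility,
                move_p,
            )
        movers = active & alive & (rng.random(n) < move_p)
        if movers.any():
            current[movers] = rng.integers(1, len(units), movers.sum())

    exposed_base = residence[:, base_year - y0] == 0

    # --- service-line linkage (students ever resident in the treated unit) ---
    ever_treated = (residence == 0).any(axis=1)
    is_lead = rng_link.random(n) < config.lead_share
    matched = ever_treated & (rng_link.random(n) < config.match_rate)
    material = np.where(
        is_lead, np.where(rng_link.random(n) < 0.1, "galvanized steel", "lead"), "copper"
    )

    # --- expand to student-year rows ------------------------------------------
    stud_idx, year_idx = np.where(residence >= 0)
    year_vals = years[year_idx]
    d_idx = residence[stud_idx, year_idx]
    grade = year_vals - entry[stud_idx]
    in_treated_now = d_idx == 0
    is_post = year_vals >= config.treatment_year
    carries = (exposed_base[stud_idx] | in_treated_now) & is_post

    attends_other = rng.random(len(stud_idx)) < config.attend_other_rate
    attended = d_idx.copy()
    if attends_other.any():
        attended[attends_other] = rng.integers(0, len(units), attends_other.sum())

    grade_s = (grade >= 6).astype(int)
    sl_s = is_lead[stud_idx].astype(int)
    shares = {
        "gender": config.subgroups.get("gender", SubgroupSpec()).share_s1,
        "grade_band": 0.5,
        "ses": 0.5,
        "service_line": config.lead_share,
    }
    s_values = {
        "gender": gender_s[stud_idx],
        "grade_band": grade_s,
        "ses": ses_s1[stud_idx],
        "service_line": sl_s,
    }

    taus = {o: config.att_by_year(o) for o in outcomes}
    records = pd.DataFrame(
        {
            "student_id": [f"S{i:06d}" for i in stud_idx],
            "year": year_vals.astype(int),
            "district_of_residence": [units[d] for d in d_idx],
            "district_attended": [units[d] for d in attended],
            "grade": grade.astype(int),
            "gender": np.where(gender_s[stud_idx] == 1, "female", "male"),
        }
    )

    for o in outcomes:
        spec = config.outcomes[o]
        mu = base[d_idx, year_idx, oi[o]].copy()
        tau_vec = np.array([taus[o].get(int(y), 0.0) for y in year_vals])
        mu = mu + np.where(carries, tau_vec, 0.0)
        for var, sg in config.subgroups.items():
            ld = sg.level_diff.get(o, 0.0)
            ed = sg.effect_diff.get(o, 0.0)
            if ld:
                mu += (s_values[var] - shares[var]) * ld
            if ed:
                # treated-unit effect heterogeneity only applies to service
                # lines inside the treated unit; other variables exist state
                # wide but the offsets only matter where effects occur
                mu += np.where(carries, (s_values[var] - shares[var]) * ed, 0.0)
        mu += spec.ability_loading * ability[stud_idx]
        observed = year_vals >= spec.first_year
        if spec.grades is not None:
            observed &= (grade >= spec.grades[0]) & (grade <= spec.grades[1])
        if spec.kind == "binary":
            p = np.clip(mu, 0.005, 0.995)
            val = (rng.random(len(stud_idx)) < p).astype(float)
        elif spec.kind == "rate":
            val = np.clip(mu + rng.normal(0, spec.student_sd, len(stud_idx)), 0.0, 1.0)
        else:
            val = mu + rng.normal(0, spec.student_sd, len(stud_idx))
        from .panel import OUTCOME_COLUMNS

        records[OUTCOME_COLUMNS[o]] = np.where(observed, val, np.nan)

    u = ses_latent[stud_idx]
    records["econ_disadvantaged"] = (
        rng.random(len(stud_idx)) < _sigmoid(1.9 + 1.3 * u)
    ).astype(int)
    records["snap"] = (rng.random(len(stud_idx)) < _sigmoid(0.2 + 1.3 * u)).astype(int)
    records["tanf"] = (rng.random(len(stud_idx)) < _sigmoid(-1.2 + 1.3 * u)).astype(int)
    records["graduated_flag"] = (
        (grade == 12) & graduated[stud_idx]
    ).astype(int)
    has_addr = matched[stud_idx]
    records["address_key"] = np.where(
        has_addr, np.char.add("ADDR", np.char.zfill(stud_idx.astype(str), 6)), None
    )
    records["service_line_material"] = np.where(has_addr, material[stud_idx], None)
    return records.sort_values(["student_id", "year"], ignore_index=True), truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def stress_config(config: SyntheticConfig | None = None, strength: float = 0.25) -> SyntheticConfig:
    """Config variant with outcome-correlated post-treatment attrition switched on."""
    config = config or SyntheticConfig()
    return replace(config, selective_mobility=strength)
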