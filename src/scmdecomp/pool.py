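"""Rule-based restriction of the candidate control-district pool.

A treated district with extreme demographics (very high fraction Black and
fraction economically disadvantaged) has few natural comparisons, so the
donor pool is restricted to districts that are themselves extreme on those
covariates.  Three preset schemes are supported: the union of the top
deciles of the two covariates (U90, the primary sample), the intersection
of the top quartiles (I75), and the union of the top 5% tails (U95) —
always after dropping districts with fewer than 1000 students.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, EmptyPoolError, SchemaError

REQUIRED_COVARIATES = ["district_id", "enrollment", "fraction_black", "fraction_econ_disadvantaged"]


@dataclass(frozen=True)
class PoolRule:
    """Donor-pool restriction rule.

    ``percentile`` is applied to both fraction Black and fraction
    economically disadvantaged ("top (100-p)%" means at or above the
    nearest-rank p-th percentile); ``combinator`` joins the two tail sets.
    """

    min_enrollment: int = 1000
    combinator: str = "union"
    percentile: float = 90.0
    reference_year: int = 2014

    def __post_init__(self):
        if self.combinator not in ("union", "intersection"):
            raise ConfigError(f"unknown combinator {self.combinator!r}")
        if not (0 < self.percentile <= 100):
            raise ConfigError("percentile must lie in (0, 100]")
        if self.min_enrollment < 0:
            raise ConfigError("min_enrollment must be nonnegative")


#: The primary sample and the two robustness pools.
PRESETS = {
    "U90": PoolRule(combinator="union", percentile=90.0),
    "I75": PoolRule(combinator="intersection", percentile=75.0),
    "U95": PoolRule(combinator="union", percentile=95.0),
}


@dataclass
class PoolResult:
    controls: list
    cutoffs: dict
    n_dropped_small: int


def _nearest_rank_cutoff(values: pd.Series, percentile: float) -> float:
    """Inclusive nearest-rank percentile: the value at rank ceil(p/100 * n)."""
    ordered = values.sort_values().to_numpy()
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return float(ordered[rank - 1])


def restrict_pool(covariates: pd.DataFrame, rule: PoolRule, treated_id) -> PoolResult:
    """Apply a :class:`PoolRule` to a district covariate table.

    Small districts are removed first; percentile cutoffs are then computed
    over the remaining districts *excluding the treated unit*, so the
    treated district's extreme covariate values cannot shift its own
    comparison pool.  The treated unit is never returned.
    """
    missing = [c for c in REQUIRED_COVARIATES if c not in covariates.columns]
    if missing:
        raise SchemaError(f"covariate table missing column(s): {missing}")
    cov = covariates.copy()
    if "year" in cov.columns and cov["year"].nunique() > 1:
        cov = cov[cov["year"] == rule.reference_year]
    if treated_id not in set(cov["district_id"]):
        raise SchemaError(f"treated district {treated_id!r} not in covariate table")

    large = cov[cov["enrollment"] >= rule.min_enrollment]
    n_dropped = len(cov) - len(large)
    candidates = large[large["district_id"] != treated_id]
    if candidates.empty:
        raise EmptyPoolError("no candidate districts pass the enrollment filter")

    cutoffs = {
        "fraction_black": _nearest_rank_cutoff(candidates["fraction_black"], rule.percentile),
        "fraction_econ_disadvantaged": _nearest_rank_cutoff(
            candidates["fraction_econ_disadvantaged"], rule.percentile
        ),
    }
    in_black = candidates["fraction_black"] >= cutoffs["fraction_black"]
    in_econ = candidates["fraction_econ_disadvantaged"] >= cutoffs["fraction_econ_disadvantaged"]
    mask = (in_black | in_econ) if rule.combinator == "union" else (in_black & in_econ)
    pool = candidates.loc[mask, "district_id"].tolist()
    if not pool:
        raise EmptyPoolError(
            f"pool rule ({rule.combinator} at percentile {rule.percentile}) left no districts"
        )
    return PoolResult(controls=sorted(pool, key=str), cutoffs=cutoffs, n_dropped_small=n_dropped)
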