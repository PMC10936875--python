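import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_panel(values: dict, treatment_year: int = 2015) -> pd.DataFrame:
    """Long panel from {outcome: {unit: {year: value}}}."""
    rows = []
    for outcome, units in values.items():
        for unit, series in units.items():
            for year, value in series.items():
                rows.append((unit, year, outcome, float(value)))
    panel = pd.DataFrame(rows, columns=["unit", "year", "outcome", "value"])
    panel["n"] = 1
    panel["period"] = np.where(panel["year"] < treatment_year, "pre", "post")
    return panel


@pytest.fixture
def toy_panel():
    """3 districts x 4 years, one outcome, hand-checkable values.

    Post-minus-pre diffs: treated 2.0, control A 1.5, control B 0.5.
    """
    return make_panel(
        {
            "math": {
                "T": {2013: 1.0, 2014: 2.0, 2015: 3.0, 2016: 4.0},
                "A": {2013: 0.0, 2014: 1.0, 2015: 2.0, 2016: 2.0},
                "B": {2013: 2.0, 2014: 2.0, 2015: 2.0, 2016: 3.0},
            }
        }
    )


@pytest.fixture
def student_records():
    """Six hand-written student-year rows across two districts."""
    return pd.DataFrame(
        {
            "student_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "year": [2014, 2015, 2014, 2015, 2014, 2015],
            "district_of_residence": ["T", "T", "T", "T", "A", "A"],
            "district_attended": ["T", "T", "T", "T", "A", "A"],
            "grade": [4, 5, 5, 6, 6, 7],
            "gender": ["male", "male", "female", "female", "male", "male"],
            "math_score": [-1.0, -0.5, 1.0, 0.5, 0.0, 0.2],
            "reading_score": [0.5, np.nan, -0.5, 0.1, 0.3, 0.4],
            "special_needs": [0, 0, 1, 1, 0, 0],
            "attendance_rate": [0.95, 0.90, 0.85, 0.88, 0.99, 0.97],
            "econ_disadvantaged": [1, 1, 0, 1, 0, 0],
            "snap": [1, 0, 0, 0, 0, 0],
            "tanf": [0, 0, 0, 0, 0, 0],
            "graduated_flag": [0, 0, 0, 0, 0, 0],
            "address_key": ["a1", "a1", None, None, None, None],
        }
    )
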