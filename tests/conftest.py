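import numpy as np
import pandas as pd
import pytest

from densitycal import io as dio
from densitycal.synthetic import CHECKLIST_COLUMNS, make_fixture_scenario


@pytest.fixture(scope="session")
def common_scenario():
    return make_fixture_scenario("common", 7)


@pytest.fixture(scope="session")
def common_data(common_scenario):
    return dio.prepare_datasets(common_scenario, 7)


def make_checklist(**overrides) -> dict:
    """One valid community checklist row; override fields as needed."""
    row = {
        "survey_id": "C0000", "x_m": 500.0, "y_m": 500.0, "jday": 150.0,
        "min_since_dawn": 60.0, "duration_min": 10.0, "protocol": "stationary",
        "location_type": "personal", "observer_id": "obs01", "complete": True,
        "count": 3.0, "is_x": False,
    }
    row.update(overrides)
    return row


def checklist_frame(rows) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=CHECKLIST_COLUMNS)
    out["survey_id"] = [f"C{i:04d}" for i in range(len(out))]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
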