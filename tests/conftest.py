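import datetime as dt

import numpy as np
import pandas as pd
import pytest

from isocal.io import StudyDialect
from isocal.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def dialect() -> StudyDialect:
    return StudyDialect(lights_on=dt.time(7, 0))


def make_trace_frame(rows: list[dict], lights_on: dt.time = dt.time(7, 0)) -> pd.DataFrame:
    """Build a canonical trace frame from partial row dicts.

    Each row may give ``t_min`` (minutes after the first lights-on) instead
    of a timestamp; unspecified fields get benign defaults.
    """
    base = dt.datetime(2022, 3, 1, 7, 0)
    out = []
    for i, row in enumerate(rows):
        r = {
            "mouse_id": "m1",
            "cage_id": "c1",
            "d_o2": 0.003,
            "d_co2": 0.0025,
            "d_h2": 0.0,
            "food_g": 0.1,
            "water_g": 0.1,
            "flow_lpm": 0.4,
        }
        r.update({k: v for k, v in row.items() if k != "t_min"})
        t_min = row.get("t_min", i * 24)
        r["timestamp"] = base + dt.timedelta(minutes=t_min)
        r["zt"] = (t_min / 60.0) % 24.0
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_study():
    """A small noisy study with faults, shared across tests."""
    cfg = CohortConfig(
        n_per_group={"GF": 4, "OLIGO": 4, "SPF": 4}, days=3, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = CohortConfig(
        n_per_group={"GF": 2, "OLIGO": 2, "SPF": 2}, days=3, seed=7
    ).noiseless()
    return generate_cohort(cfg)
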