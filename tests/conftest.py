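import numpy as np
import pandas as pd
import pytest

from sdvimpact.cohort_model import empty_dataset
from sdvimpact.synthetic_cohort import CohortSimParams, simulate_truth


@pytest.fixture(scope="session")
def small_params():
    return CohortSimParams(n_sites=3, patients_per_site=40, seed=7)


@pytest.fixture(scope="session")
def truth_small(small_params):
    return simulate_truth(small_params)


@pytest.fixture(scope="session")
def truth_mid():
    # larger cohort for rate-recovery style checks
    params = CohortSimParams(n_sites=9, patients_per_site=30, seed=11)
    return simulate_truth(params)


def make_tiny_dataset(patients_rows, visits=(), labs=(), art=(), events=(),
                      freeze="2015-12-31"):
    """Hand-build a DatasetVersion from row dicts (dates as ISO strings)."""
    ds = empty_dataset("truth")
    frames = {"patients": list(patients_rows), "visits": list(visits),
              "labs": list(labs), "art": list(art), "events": list(events)}
    from sdvimpact.cohort_model import DATE_COLUMNS, TABLE_COLUMNS
    for name, rows in frames.items():
        if not rows:
            continue
        df = pd.DataFrame(rows)
        for c in TABLE_COLUMNS[name]:
            if c not in df.columns:
                df[c] = None
        df = df[TABLE_COLUMNS[name]]
        for c in DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c])
        setattr(ds, name, df)
    sites = set(ds.patients["site_id"].dropna()) if len(ds.patients) else set()
    ds.freeze_dates = {s: pd.Timestamp(freeze) for s in sites}
    return ds


@pytest.fixture
def tiny_dataset_factory():
    return make_tiny_dataset
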