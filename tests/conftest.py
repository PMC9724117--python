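import numpy as np
import pandas as pd
import pytest

from cvdcompare.cohort import CohortTable, ParticipantRecord


def make_record(**overrides) -> ParticipantRecord:
    base = dict(
        id="P0",
        age=55.0,
        sex="male",
        sbp=125.0,
        dbp=78.0,
        bp_treated=False,
        total_chol=5.2,
        hdl_chol=1.2,
        smoking="never",
        diabetes=False,
        family_history_cvd=False,
        on_art=True,
        cd4_latest=469.0,
        bmi=24.0,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


def make_frame(n=20, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    tc = rng.uniform(3.0, 7.0, n)
    return pd.DataFrame({
        "id": [f"P{i}" for i in range(n)],
        "age": rng.uniform(30, 75, n),
        "sex": rng.choice(["male", "female"], n),
        "sbp": rng.uniform(95, 175, n),
        "dbp": rng.uniform(60, 100, n),
        "bp_treated": rng.random(n) < 0.1,
        "total_chol": tc,
        "hdl_chol": np.minimum(rng.uniform(0.8, 2.5, n), 0.6 * tc),
        "smoking": rng.choice(["current", "ex", "never"], n),
        "diabetes": rng.random(n) < 0.05,
        "hba1c": rng.normal(5.5, 0.5, n),
        "bmi": rng.uniform(18, 35, n),
        "family_history_cvd": rng.random(n) < 0.17,
        "on_art": rng.random(n) < 0.87,
        "cd4_latest": rng.lognormal(np.log(469), 0.55, n),
        "exposure_years_pi_indinavir": np.where(rng.random(n) < 0.05,
                                                rng.exponential(2, n), 0.0),
        "exposure_years_pi_lopinavir": np.where(rng.random(n) < 0.1,
                                                rng.exponential(2, n), 0.0),
        "abacavir_current": rng.random(n) < 0.03,
        "established_cvd": np.zeros(n, dtype=bool),
        "bp_device_validated": np.ones(n, dtype=bool),
        "race": "black",
    })


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(make_frame(20, seed=0), provenance="fixture")


@pytest.fixture
def record() -> ParticipantRecord:
    return make_record()
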