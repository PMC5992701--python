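import numpy as np
import pandas as pd
import pytest

import metsmarkov as mm
from metsmarkov.states import STATE_LABELS


@pytest.fixture(scope="session")
def fixture_matrices():
    return mm.load_fixture_matrices()


@pytest.fixture(scope="session")
def men_young(fixture_matrices):
    return fixture_matrices[mm.GroupKey(mm.Sex.MALE, mm.AgeBand.YOUNG)]


def classified_frame_from_sequences(seqs: pd.DataFrame, sex="male", age=30) -> pd.DataFrame:
    """Minimal classified-panel table from a state-sequence table."""
    return pd.DataFrame(
        {
            "subject_id": seqs["subject_id"].to_numpy(),
            "visit_year": 2010 + seqs["visit_index"].to_numpy(),
            "sex": sex,
            "age_years": age,
            "state": [STATE_LABELS[s] for s in seqs["state"]],
        }
    )


def random_stochastic_matrix(rng: np.random.Generator) -> np.ndarray:
    m = rng.random((7, 7)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)


@pytest.fixture
def make_record():
    def _make(**overrides):
        base = dict(
            subject_id="s1",
            visit_year=2010,
            sex="male",
            age_years=30,
            sbp=120.0,
            dbp=80.0,
            bmi=22.0,
            fasting_glucose=5.0,
            tg=1.2,
            hdl=1.3,
        )
        base.update(overrides)
        return mm.CheckupRecord(**base)

    return _make
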