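import numpy as np
import pandas as pd
import pytest

from hccscreen import CohortConfig, generate_cohort


def events_frame(offsets, codes=None, patient_id="P1"):
    """Build a one-patient imaging-claims frame from month offsets."""
    offsets = list(offsets)
    if codes is None:
        codes = ["76700"] * len(offsets)
    return pd.DataFrame(
        {
            "patient_id": [patient_id] * len(offsets),
            "month_offset": offsets,
            "procedure_code": codes,
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized default-parameter cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=4000, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """Null-benefit cohort: no true screening effect, homogeneous sojourn,
    no stage shift, no competing mortality. Observed screen-vs-clinical
    differences are pure lead-time artifact."""
    cfg = CohortConfig(
        n_patients=20000,
        seed=123,
        slow_fraction=0.0,
        slow_theta=1.0,
        true_screening_log_hr=0.0,
        stage_shift_prob_screen=0.15,
        stage_prob_clinical=0.15,
        other_cause_hazard_per_month=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
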