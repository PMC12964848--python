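import numpy as np
import pandas as pd
import pytest

from dfu_trajectory.cohort_model import build_cohort
from dfu_trajectory.synthetic_cohort import CohortSimConfig, generate_cohort


def make_cohort_frame(wounds: dict[str, list[tuple[str, str]]], onset: str | None = None,
                      **extra_cols) -> pd.DataFrame:
    """Hand-built cohort frame: wound_id -> [(date, phase), ...].

    All wounds share one patient per wound unless a wound id contains '/',
    in which case the prefix is the patient id.
    """
    rows = []
    for wid, visits in wounds.items():
        pid = wid.split("/")[0]
        first = min(d for d, _ in visits)
        for date, phase in visits:
            row = {
                "patient_id": pid,
                "wound_id": wid,
                "appointment_date": date,
                "wound_onset_date": onset or first,
                "healing_phase": phase,
            }
            row.update(extra_cols)
            rows.append(row)
    return pd.DataFrame(rows)


def make_cohort(wounds, onset=None, **extra_cols):
    return build_cohort(make_cohort_frame(wounds, onset, **extra_cols))


def planted_signal_config(seed: int, n_patients: int = 300) -> CohortSimConfig:
    """Study condition for parameter-recovery experiments: a strong planted
    effect of the gap to the next appointment on regression odds."""
    return CohortSimConfig(
        n_patients=n_patients,
        seed=seed,
        planted_effects={"days_to_next_appointment": 1.0},
    )


@pytest.fixture(scope="session")
def default_cohort_500():
    """Defaults at n=500 — used for marginal-structure checks."""
    cohort, truth = generate_cohort(CohortSimConfig(n_patients=500, seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small defaults cohort for plumbing tests."""
    cohort, truth = generate_cohort(CohortSimConfig(n_patients=60, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def planted_cohort_300():
    cohort, truth = generate_cohort(planted_signal_config(seed=11))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
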