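import numpy as np
import pandas as pd
import pytest

from pedmet.growth import GrowthReference, load_reference
from pedmet.phenotype import load_outcome_definitions
from pedmet.records import Measurement, PatientRecord


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def definitions():
    return load_outcome_definitions()


def make_flat_reference(L: float, M: float, S: float) -> GrowthReference:
    """A reference with constant L/M/S at every age, for hand-checkable math."""
    rows = [
        (sex, agemos, L, M, S)
        for sex in ("male", "female")
        for agemos in range(24, 217, 12)
    ]
    return GrowthReference(pd.DataFrame(rows, columns=["sex", "agemos", "L", "M", "S"]))


@pytest.fixture
def flat_ref():
    return make_flat_reference(L=1.0, M=16.0, S=0.1)


def patient_with_bmis(records, sex="male", pid="X", height_cm=100.0, **kwargs):
    """Patient whose measurements realize the given (age, bmi) pairs exactly
    (height fixed at 100 cm so weight in kg equals BMI)."""
    meas = [Measurement(age, height_cm, bmi * (height_cm / 100.0) ** 2) for age, bmi in records]
    return PatientRecord(patient_id=pid, sex=sex, measurements=meas, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    from pedmet.simulate import SimulationConfig, generate_cohort

    return generate_cohort(SimulationConfig(n_patients=300, seed=11))
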