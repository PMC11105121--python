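"""Patient-level domain types and the flat-file EHR schema.

All events are timestamped in fractional years of age (no calendar dates);
cohort windows downstream are age-based.  A :class:`PatientSet` maps onto six
delimited text tables::

    demographics.csv  patient_id, sex, race, insurance
    measurements.csv  patient_id, age, height_cm, weight_kg
    encounters.csv    patient_id, age
    diagnoses.csv     patient_id, age, code
    labs.csv          patient_id, age, analyte, value
    medications.csv   patient_id, age, name
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple


class Measurement(NamedTuple):
    age: float
    height_cm: float
    weight_kg: float


class Diagnosis(NamedTuple):
    age: float
    code: str  # ICD-9 or ICD-10 string, verbatim


class Lab(NamedTuple):
    age: float
    analyte: str
    value: float


class MedicationOrder(NamedTuple):
    age: float
    name: str


@dataclasses.dataclass
class PatientRecord:
    """One child's full event history."""

    patient_id: str
    sex: str
    race: str = "unknown"
    insurance: str = "unknown"
    measurements: list[Measurement] = dataclasses.field(default_factory=list)
    encounters: list[float] = dataclasses.field(default_factory=list)
    diagnoses: list[Diagnosis] = dataclasses.field(default_factory=list)
    labs: list[Lab] = dataclasses.field(default_factory=list)
    medications: list[MedicationOrder] = dataclasses.field(default_factory=list)

    def sorted(self) -> "PatientRecord":
        """Copy with every event stream in age order (stable)."""
        return dataclasses.replace(
            self,
            measurements=sorted(self.measurements),
            encounters=sorted(self.encounters),
            diagnoses=sorted(self.diagnoses),
            labs=sorted(self.labs),
            medications=sorted(self.medications),
        )


@dataclasses.dataclass
class PatientSet:
    """A collection of patients plus provenance of how it was produced.

    ``truth`` carries the simulator's latent case indicator when the set was
    produced by :func:`pedmet.simulate.generate_cohort`; it exists for tests
    and validation only and is never written to, or read from, the flat files.
    """

    patients: list[PatientRecord]
    provenance: dict = dataclasses.field(default_factory=dict)
    truth: dict[str, int] | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient identifiers must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}
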