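"""Read and write the flat-file EHR schema.

Files are delimited text with a header row; comma is the default separator
and tab is accepted.  Event tables other than demographics may be absent, in
which case patients simply carry no events of that kind.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .growth import GrowthReference, bmi_percentile, compute_bmi
from .records import Diagnosis, Lab, Measurement, MedicationOrder, PatientRecord, PatientSet

__all__ = ["LoadReport", "SchemaError", "read_patient_tables", "write_patient_tables"]

TABLE_COLUMNS = {
    "demographics": ["patient_id", "sex", "race", "insurance"],
    "measurements": ["patient_id", "age", "height_cm", "weight_kg"],
    "encounters": ["patient_id", "age"],
    "diagnoses": ["patient_id", "age", "code"],
    "labs": ["patient_id", "age", "analyte", "value"],
    "medications": ["patient_id", "age", "name"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


@dataclasses.dataclass
class LoadReport:
    """Row-level accounting for one load: what was kept and what was dropped."""

    n_patients: int = 0
    n_measurements: int = 0
    dropped_nonpositive: int = 0
    dropped_outlier_z: int = 0
    row_errors: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)


def _read_table(path: Path, name: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path, sep=sep, dtype={"patient_id": str}, float_precision="round_trip"
    )
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _clean_ages(df: pd.DataFrame, name: str, report: LoadReport) -> pd.DataFrame:
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = ages.isna() | (ages < 0)
    for idx in df.index[bad]:
        report.row_errors.append((name, int(idx), f"unparseable or negative age {df.loc[idx, 'age']!r}"))
    df = df.loc[~bad].copy()
    df["age"] = ages.loc[~bad].astype(float)
    return df


def read_patient_tables(
    directory: str | Path,
    *,
    ref: GrowthReference | None = None,
    z_max: float = 8.0,
) -> tuple[PatientSet, LoadReport]:
    """Load a PatientSet from a directory of schema tables.

    Measurement rows with nonpositive height or weight are dropped and
    counted.  When a growth reference is supplied, measurements whose BMI
    z-score magnitude exceeds ``z_max`` are additionally dropped as recording
    outliers (ages outside the reference are left untouched).
    """
    directory = Path(directory)
    report = LoadReport()

    demo_path = directory / "demographics.csv"
    if not demo_path.exists():
        raise FileNotFoundError(f"required table missing: {demo_path}")
    demo = _read_table(demo_path, "demographics")

    patients: dict[str, PatientRecord] = {}
    for row in demo.itertuples(index=False):
        patients[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            sex=str(row.sex),
            race=str(row.race),
            insurance=str(row.insurance),
        )

    tables: dict[str, pd.DataFrame] = {}
    for name in ("measurements", "encounters", "diagnoses", "labs", "medications"):
        path = directory / f"{name}.csv"
        if path.exists():
            tables[name] = _clean_ages(_read_table(path, name), name, report)

    if "measurements" in tables:
        meas = tables["measurements"]
        h = pd.to_numeric(meas["height_cm"], errors="coerce")
        w = pd.to_numeric(meas["weight_kg"], errors="coerce")
        bad = h.isna() | w.isna() | (h <= 0) | (w <= 0)
        report.dropped_nonpositive = int(bad.sum())
        meas = meas.loc[~bad]
        sex_of = {pid: rec.sex for pid, rec in patients.items()}
        for row in meas.itertuples(index=False):
            rec = patients.get(row.patient_id)
            if rec is None:
                report.row_errors.append(("measurements", -1, f"unknown patient {row.patient_id}"))
                continue
            height, weight = float(row.height_cm), float(row.weight_kg)
            if ref is not None:
                try:
                    z, _ = bmi_percentile(
                        compute_bmi(weight, height), row.age, sex_of[row.patient_id], ref
                    )
                except ValueError:
                    z = 0.0  # age outside reference: cannot judge, keep
                if abs(z) > z_max:
                    report.dropped_outlier_z += 1
                    continue
            rec.measurements.append(Measurement(row.age, height, weight))

    if "encounters" in tables:
        for row in tables["encounters"].itertuples(index=False):
            if row.patient_id in patients:
                patients[row.patient_id].encounters.append(float(row.age))
    if "diagnoses" in tables:
        for row in tables["diagnoses"].itertuples(index=False):
            if row.patient_id in patients:
                patients[row.patient_id].diagnoses.append(Diagnosis(row.age, str(row.code)))
    if "labs" in tables:
        for row in tables["labs"].itertuples(index=False):
            if row.patient_id in patients:
                patients[row.patient_id].labs.append(Lab(row.age, str(row.analyte), float(row.value)))
    if "medications" in tables:
        for row in tables["medications"].itertuples(index=False):
            if row.patient_id in patients:
                patients[row.patient_id].medications.append(MedicationOrder(row.age, str(row.name)))

    records = [rec.sorted() for rec in patients.values()]
    report.n_patients = len(records)
    report.n_measurements = sum(len(r.measurements) for r in records)
    pset = PatientSet(patients=records, provenance={"source": str(directory)})
    return pset, report


def write_patient_tables(pset: PatientSet, directory: str | Path, sep: str = ",") -> None:
    """Write a PatientSet to the six schema tables under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    demo, meas, enc, dx, labs, meds = [], [], [], [], [], []
    for p in pset:
        demo.append((p.patient_id, p.sex, p.race, p.insurance))
        meas.extend((p.patient_id, m.age, m.height_cm, m.weight_kg) for m in p.measurements)
        enc.extend((p.patient_id, a) for a in p.encounters)
        dx.extend((p.patient_id, d.age, d.code) for d in p.diagnoses)
        labs.extend((p.patient_id, lab.age, lab.analyte, lab.value) for lab in p.labs)
        meds.extend((p.patient_id, m.age, m.name) for m in p.medications)

    for name, rows in (
        ("demographics", demo),
        ("measurements", meas),
        ("encounters", enc),
        ("diagnoses", dx),
        ("labs", labs),
        ("medications", meds),
    ):
        pd.DataFrame(rows, columns=TABLE_COLUMNS[name]).to_csv(
            directory / f"{name}.csv", index=False, sep=sep, float_format="%.17g"
        )
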