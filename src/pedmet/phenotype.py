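"""Rule-based outcome labelling and cohort inclusion filters.

Cases are children with at least one qualifying event for the target outcome
between ages 2 and 18.  Three definitions ship by default (see
``data/outcomes.yaml``):

* **t2d** — an eMERGE-style composite: a type-2 diabetes ICD code plus
  supporting evidence (an antidiabetic medication or a qualifying glucose /
  HbA1c lab), with patients carrying only type-1 codes excluded.
* **metabolic_syndrome** — an ICD code (277.7 / E88.81) or the IDF pediatric
  composite: central adiposity (BMI percentile as waist proxy) plus at least
  two of raised triglycerides, low HDL, raised blood pressure, raised fasting
  glucose.
* **prediabetes** — an ICD code (790.2x / R73.x) or glucose criteria
  (fasting glucose 100-125 mg/dL, HbA1c 5.7-6.4%).

Every threshold and code list is configuration, not code: definitions load
from YAML and any rule can be edited or replaced.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .growth import GrowthReference, bmi_percentile, compute_bmi
from .records import PatientRecord

__all__ = [
    "LabRule",
    "OutcomeDefinition",
    "Label",
    "UnitError",
    "load_outcome_definitions",
    "label_outcome",
    "is_active_patient",
    "passes_inclusion",
]

AGE_RANGE = (2.0, 18.0)

#: canonical units per analyte; a rule using different units raises UnitError
CANONICAL_UNITS = {
    "fpg": "mg/dL",
    "random_glucose": "mg/dL",
    "hba1c": "%",
    "tg": "mg/dL",
    "hdl": "mg/dL",
    "sbp": "mmHg",
    "dbp": "mmHg",
}


class UnitError(ValueError):
    """A lab rule's units do not match the analyte's canonical units."""


@dataclasses.dataclass(frozen=True)
class LabRule:
    analyte: str
    op: str  # ">=", ">", "<", "<=", "between"
    value: float | tuple[float, float]
    units: str
    group: str | None = None

    def __post_init__(self) -> None:
        canonical = CANONICAL_UNITS.get(self.analyte)
        if canonical is not None and self.units != canonical:
            raise UnitError(
                f"analyte {self.analyte!r} expects units {canonical!r}, rule has {self.units!r}"
            )

    def fires(self, value: float) -> bool:
        if self.op == ">=":
            return value >= self.value
        if self.op == ">":
            return value > self.value
        if self.op == "<":
            return value < self.value
        if self.op == "<=":
            return value <= self.value
        if self.op == "between":
            lo, hi = self.value
            return lo <= value <= hi
        raise ValueError(f"unknown comparator {self.op!r}")

    @property
    def key(self) -> str:
        return self.group or self.analyte


@dataclasses.dataclass(frozen=True)
class IDFComposite:
    """Central adiposity plus >= min_components distinct metabolic components."""

    adiposity_bmi_percentile: float
    min_components: int
    components: tuple[LabRule, ...]


@dataclasses.dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    icd_codes: frozenset[str]
    lab_rules: tuple[LabRule, ...] = ()
    med_classes: frozenset[str] = frozenset()
    exclusion_icd: frozenset[str] = frozenset()
    combo: str = "any"  # "any" or "icd_and_support"
    idf: IDFComposite | None = None
    onset_mean: float | None = None
    age_range: tuple[float, float] = AGE_RANGE

    def __post_init__(self) -> None:
        if not self.icd_codes and not self.lab_rules and self.idf is None:
            raise ValueError("outcome definition needs ICD codes, lab rules, or a composite")


@dataclasses.dataclass
class Label:
    patient_id: str
    outcome: str
    is_case: int
    onset_age: float | None
    evidence: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.is_case) != (self.onset_age is not None):
            raise ValueError("is_case and onset_age presence must agree")


def _parse_rule(raw: dict) -> LabRule:
    value = raw["value"]
    if isinstance(value, (list, tuple)):
        value = (float(value[0]), float(value[1]))
    else:
        value = float(value)
    return LabRule(raw["analyte"], raw["op"], value, raw["units"], raw.get("group"))


def load_outcome_definitions(path: str | Path | None = None) -> dict[str, OutcomeDefinition]:
    """Load outcome definitions from YAML (the bundled defaults when path is None)."""
    if path is None:
        with resources.files("pedmet").joinpath("data/outcomes.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, OutcomeDefinition] = {}
    for name, spec in raw.items():
        idf = None
        if "idf" in spec:
            idf = IDFComposite(
                adiposity_bmi_percentile=float(spec["idf"]["adiposity_bmi_percentile"]),
                min_components=int(spec["idf"]["min_components"]),
                components=tuple(_parse_rule(r) for r in spec["idf"]["components"]),
            )
        out[name] = OutcomeDefinition(
            name=name,
            icd_codes=frozenset(str(c) for c in spec.get("icd_codes", [])),
            lab_rules=tuple(_parse_rule(r) for r in spec.get("lab_rules", [])),
            med_classes=frozenset(m.lower() for m in spec.get("med_classes", [])),
            exclusion_icd=frozenset(str(c) for c in spec.get("exclusion_icd", [])),
            combo=spec.get("combo", "any"),
            idf=idf,
            onset_mean=spec.get("onset_mean"),
        )
    return out


def code_matches(code: str, rule_codes: frozenset[str]) -> bool:
    """Exact match, or hierarchical match on a rule prefix (E11 matches E11.65)."""
    code = code.strip()
    return code in rule_codes or any(code.startswith(rc + ".") for rc in rule_codes)


def _in_range(age: float, rng: tuple[float, float]) -> bool:
    return rng[0] <= age <= rng[1]


def _idf_onset(
    patient: PatientRecord, idf: IDFComposite, rng: tuple[float, float], ref: GrowthReference
) -> tuple[float, list[tuple[str, str]]] | None:
    """Age at which the IDF composite completes, or None if it never does."""
    adiposity_age = None
    for m in patient.measurements:
        if not _in_range(m.age, rng):
            continue
        try:
            _, pct = bmi_percentile(compute_bmi(m.weight_kg, m.height_cm), m.age, patient.sex, ref)
        except ValueError:
            continue
        if pct >= idf.adiposity_bmi_percentile:
            adiposity_age = m.age
            break
    if adiposity_age is None:
        return None
    first_fire: dict[str, float] = {}
    for lab in patient.labs:
        if not _in_range(lab.age, rng):
            continue
        for rule in idf.components:
            if rule.analyte == lab.analyte and rule.fires(lab.value):
                first_fire[rule.key] = min(first_fire.get(rule.key, lab.age), lab.age)
    if len(first_fire) < idf.min_components:
        return None
    ages = sorted(first_fire.values())
    completing = ages[idf.min_components - 1]
    onset = max(adiposity_age, completing)
    evidence = [("idf:adiposity", f"bmi_percentile>= {idf.adiposity_bmi_percentile} at age {adiposity_age:.2f}")]
    evidence += [(f"idf:{k}", f"first at age {a:.2f}") for k, a in sorted(first_fire.items())]
    return onset, evidence


def label_outcome(
    patient: PatientRecord, defn: OutcomeDefinition, ref: GrowthReference | None = None
) -> Label:
    """Apply one outcome definition to one patient.

    ``is_case`` is 1 iff any rule fires within the definition's age range;
    ``onset_age`` is the age of the earliest firing rule and ``evidence``
    lists every rule that fired.  The IDF composite (metabolic syndrome)
    requires a growth reference for the adiposity proxy; without one it is
    skipped.
    """
    rng = defn.age_range
    firing: list[tuple[float, str, str]] = []  # (onset contribution, rule, event)

    icd_hits = [
        d for d in patient.diagnoses if _in_range(d.age, rng) and code_matches(d.code, defn.icd_codes)
    ]
    lab_hits = [
        (lab, rule)
        for lab in patient.labs
        if _in_range(lab.age, rng)
        for rule in defn.lab_rules
        if rule.analyte == lab.analyte and rule.fires(lab.value)
    ]
    med_hits = [
        m
        for m in patient.medications
        if _in_range(m.age, rng) and m.name.lower() in defn.med_classes
    ]

    if defn.combo == "icd_and_support":
        excluded = bool(defn.exclusion_icd) and not icd_hits and any(
            _in_range(d.age, rng) and code_matches(d.code, defn.exclusion_icd)
            for d in patient.diagnoses
        )
        if icd_hits and (med_hits or lab_hits) and not excluded:
            onset = min(d.age for d in icd_hits)
            firing.append((onset, "icd", f"{icd_hits[0].code} at age {onset:.2f}"))
            for m in med_hits:
                firing.append((onset, "medication", f"{m.name} at age {m.age:.2f}"))
            for lab, rule in lab_hits:
                firing.append((onset, f"lab:{rule.analyte}", f"{lab.value} at age {lab.age:.2f}"))
    elif defn.combo == "any":
        for d in icd_hits:
            firing.append((d.age, "icd", f"{d.code} at age {d.age:.2f}"))
        for lab, rule in lab_hits:
            firing.append((lab.age, f"lab:{rule.analyte}", f"{lab.value} at age {lab.age:.2f}"))
        if defn.idf is not None and ref is not None:
            hit = _idf_onset(patient, defn.idf, rng, ref)
            if hit is not None:
                onset, evidence = hit
                for rule, event in evidence:
                    firing.append((onset, rule, event))
    else:
        raise ValueError(f"unknown combo {defn.combo!r}")

    if not firing:
        return Label(patient.patient_id, defn.name, 0, None)
    onset = min(f[0] for f in firing)
    return Label(patient.patient_id, defn.name, 1, onset, [(r, e) for _, r, e in sorted(firing)])


def is_active_patient(patient: PatientRecord, gap_years: float = 3.0) -> bool:
    """True iff the patient keeps contact after age 12: no gap longer than
    ``gap_years`` in {12} | {encounter ages in (12, 18]} | {18}."""
    anchors = sorted({12.0, 18.0} | {a for a in patient.encounters if 12.0 < a <= 18.0})
    return all(b - a <= gap_years for a, b in zip(anchors, anchors[1:]))


def passes_inclusion(patient: PatientRecord, ref: GrowthReference) -> bool:
    """Cohort entry filter: at least two height/weight records from different
    months (>= 1/12 year apart), at least one BMI at or above the overweight
    percentile (85th), and sustained activity after age 12."""
    ages = [m.age for m in patient.measurements]
    if len(ages) < 2 or (max(ages) - min(ages)) < 1.0 / 12.0:
        return False
    overweight = False
    for m in patient.measurements:
        try:
            _, pct = bmi_percentile(compute_bmi(m.weight_kg, m.height_cm), m.age, patient.sex, ref)
        except ValueError:
            continue
        if pct >= 85.0:
            overweight = True
            break
    return overweight and is_active_patient(patient)
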